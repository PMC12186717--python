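"""VCF reading, site filters, masking, polarization and allele frequencies."""

import numpy as np
import pytest
from scipy.stats import binomtest

from introgrescan import (
    FilterParams,
    RegionMask,
    allele_freqs,
    apply_site_filters,
    mask_regions,
    polarize,
    read_vcf,
    write_vcf,
)
from introgrescan.core import MISSING, IntrogrescanError, SampleNotFoundError
from introgrescan.genotype_io import het_allele_balance_phred

from conftest import clean_anno, make_table

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tT\t.\t.\tMQ=60\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tG\tC\t.\t.\tMQ=55\tGT\t0/0\t./.\t0/1
chr1\t300\t.\tA\tT,G\t.\t.\tMQ=60\tGT\t0/0\t0/1\t0/2
chr1\t400\t.\tAT\tA\t.\t.\tMQ=60\tGT\t0/0\t0/1\t1/1
chr1\t500\t.\tC\tG\t.\t.\tMQ=60\tGT\t1/1\t1/1\t1/1
"""


class TestReadVcf:
    def test_biallelic_snps_only(self, tmp_path):
        """Multiallelic and indel records are dropped and counted."""
        f = tmp_path / "x.vcf"
        f.write_text(VCF_TEXT)
        t = read_vcf(f)
        assert t.n_sites == 3  # 5 records - 1 triallelic - 1 indel
        assert t.n_dropped_non_biallelic == 2
        assert list(t.pos) == [100, 200, 500]
        assert t.samples == ["a", "b", "c"]
        np.testing.assert_array_equal(t.dosage[0], [0, 1, 2])

    def test_missing_genotype_preserved(self, tmp_path):
        f = tmp_path / "x.vcf"
        f.write_text(VCF_TEXT)
        t = read_vcf(f)
        assert t.dosage[1, 1] == MISSING

    def test_missing_sample_raises(self, tmp_path):
        f = tmp_path / "x.vcf"
        f.write_text(VCF_TEXT)
        with pytest.raises(SampleNotFoundError):
            read_vcf(f, samples=["a", "zzz"])

    def test_round_trip(self, tmp_path):
        t = make_table([10, 20], [[0, 1], [2, MISSING]], anno=clean_anno(2))
        write_vcf(t, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf")
        np.testing.assert_array_equal(back.dosage, t.dosage)
        assert list(back.pos) == [10, 20]


class TestSiteFilters:
    def test_mq_below_threshold_removed(self):
        anno = clean_anno(2)
        anno["MQ"] = [49.0, 50.0]
        t = make_table([10, 20], [[0, 1], [0, 1]], anno=anno)
        out, log = apply_site_filters(t, FilterParams(depth_sd=None))
        assert list(out.pos) == [20]
        assert log.counts()["MQ"] == 1

    def test_all_passing_identity(self):
        t = make_table([10, 20, 30], [[0, 1]] * 3, samples=["a", "b"],
                       anno=clean_anno(3))
        out, log = apply_site_filters(t, FilterParams())
        assert out.n_sites == 3
        assert all(c == 0 for c in log.counts().values())
        assert log.n_removed_unique() == t.n_sites - out.n_sites == 0

    def test_proximity_rule_removes_intervening(self):
        """A passing site bracketed by two failing sites <= 10 bp apart goes."""
        anno = clean_anno(3)
        anno["MQ"] = [10.0, 60.0, 10.0]  # fail, pass, fail at 100/103/105
        t = make_table([100, 103, 105], [[0, 1]] * 3, anno=anno)
        out, log = apply_site_filters(t, FilterParams(depth_sd=None))
        assert out.n_sites == 0
        assert log.counts()["PROXIMITY"] == 1

    def test_proximity_rule_gap_beyond_10bp(self):
        anno = clean_anno(3)
        anno["MQ"] = [10.0, 60.0, 10.0]
        t = make_table([100, 106, 120], [[0, 1]] * 3, anno=anno)
        out, _ = apply_site_filters(t, FilterParams(depth_sd=None))
        assert list(out.pos) == [106]

    def test_depth_rule_mean_plus_1_5_sd(self):
        """depths {10,10,10,10,100}: cutoff = 28 + 1.5*36 = 82 removes the 100."""
        anno = clean_anno(5)
        anno["DP"] = [10.0, 10.0, 10.0, 10.0, 100.0]
        t = make_table([10, 30, 50, 70, 90], [[0, 1]] * 5, anno=anno)
        out, log = apply_site_filters(t, FilterParams())
        assert list(out.pos) == [10, 30, 50, 70]
        assert log.depth_cutoff == pytest.approx(28 + 1.5 * 36.0)

    def test_missingness_rule(self):
        d = [[MISSING, MISSING, 0, 0, 1],  # 40% missing -> removed
             [MISSING, 0, 0, 0, 1]]        # 20% -> kept (rule is strict >)
        t = make_table([10, 20], d, anno=clean_anno(2))
        out, _ = apply_site_filters(t, FilterParams(depth_sd=None))
        assert list(out.pos) == [20]

    def test_allele_balance_rule(self):
        """A het genotype with 30:2 depths fails the PHRED>20 binomial rule."""
        t = make_table([10, 20], [[1, 0], [1, 0]], anno=clean_anno(2),
                       ad_ref=[[30, 20], [10, 20]], ad_alt=[[2, 0], [10, 0]])
        out, log = apply_site_filters(t, FilterParams(depth_sd=None))
        assert list(out.pos) == [20]
        assert log.counts()["ALLELE_BALANCE"] == 1

    def test_phred_matches_exact_binomial_test(self):
        """PHRED scores agree with scipy's exact two-sided binomial test."""
        r = np.array([30, 10, 7, 0, 15])
        a = np.array([2, 10, 13, 9, 16])
        ours = het_allele_balance_phred(r, a)
        for i in range(len(r)):
            p = binomtest(int(r[i]), int(r[i] + a[i]), 0.5).pvalue
            assert ours[i] == pytest.approx(-10 * np.log10(p), rel=1e-9)

    def test_negative_depth_raises(self):
        t = make_table([10], [[1, 1]], anno=clean_anno(1),
                       ad_ref=[[5, 5]], ad_alt=[[5, 5]])
        t.anno.loc[0, "DP"] = -5.0
        with pytest.raises(IntrogrescanError):
            apply_site_filters(t, FilterParams())

    def test_filterlog_accounting(self):
        anno = clean_anno(4)
        anno["MQ"] = [10.0, 60.0, 60.0, 10.0]
        anno["MQ0F"] = [0.5, 0.0, 0.0, 0.5]  # overlaps with MQ failures
        t = make_table([10, 200, 300, 400], [[0, 1]] * 4, anno=anno)
        out, log = apply_site_filters(t, FilterParams(depth_sd=None))
        assert log.n_removed_unique() == t.n_sites - out.n_sites == 2

    def test_idempotent_with_resolved_cutoff(self):
        """Re-filtering with the recorded depth cutoff changes nothing."""
        rng = np.random.default_rng(0)
        anno = clean_anno(50)
        anno["DP"] = rng.poisson(100, 50).astype(float)
        anno["MQ"] = np.where(rng.random(50) < 0.1, 30.0, 60.0)
        t = make_table(np.arange(1, 51) * 7, rng.integers(0, 3, (50, 3)), anno=anno)
        once, log = apply_site_filters(t, FilterParams())
        params2 = FilterParams(depth_cutoff=log.depth_cutoff)
        twice, log2 = apply_site_filters(once, params2)
        assert twice.n_sites == once.n_sites
        assert all(c == 0 for c in log2.counts().values())

    def test_commutes_with_masking_outside_regions(self):
        rng = np.random.default_rng(1)
        anno = clean_anno(40)
        anno["MQ"] = np.where(rng.random(40) < 0.2, 30.0, 60.0)
        t = make_table(np.arange(1, 41) * 100, rng.integers(0, 3, (40, 2)), anno=anno)
        m = RegionMask([("chr1", 1000, 2000)])
        a, _ = apply_site_filters(mask_regions(t, m), FilterParams(depth_sd=None))
        b = mask_regions(apply_site_filters(t, FilterParams(depth_sd=None))[0], m)
        np.testing.assert_array_equal(a.pos, b.pos)


class TestMaskRegions:
    MASK = RegionMask([("chr2", 9_800_000, 32_540_000)])

    def test_inside_interval_removed(self):
        t = make_table([10_000_000], [[0, 1]], chrom=["chr2"])
        assert mask_regions(t, self.MASK).n_sites == 0

    def test_boundary_retained(self):
        t = make_table([9_799_999], [[0, 1]], chrom=["chr2"])
        assert mask_regions(t, self.MASK).n_sites == 1

    def test_empty_mask_identity(self):
        t = make_table([5, 15], [[0, 1], [1, 2]])
        out = mask_regions(t, RegionMask([]))
        assert out.n_sites == 2

    def test_bed_coordinate_conventions(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t99\t200\n")
        m0 = RegionMask.from_bed(bed, one_based=False)  # BED half-open
        m1 = RegionMask.from_bed(bed, one_based=True)
        assert m0.intervals == [("chr1", 100, 200)]
        assert m1.intervals == [("chr1", 99, 200)]


class TestPolarize:
    def test_outgroup_hom_alt_flips(self):
        t = make_table([10], [[0, 1, 2, 2]], samples=["a", "b", "c", "og"])
        out = polarize(t, "og")
        np.testing.assert_array_equal(out.dosage[0], [2, 1, 0, 0])

    def test_outgroup_hom_ref_unchanged(self):
        t = make_table([10], [[0, 1, 2, 0]], samples=["a", "b", "c", "og"])
        out = polarize(t, "og")
        np.testing.assert_array_equal(out.dosage[0], [0, 1, 2, 0])

    def test_outgroup_het_flagged_freq_half(self):
        t = make_table([10], [[0, 2, 1]], samples=["a", "b", "og"])
        out = polarize(t, "og")
        assert out.outgroup_het[0]
        assert allele_freqs(out, ["og"])[0] == 0.5

    def test_outgroup_missing_flagged(self):
        t = make_table([10], [[0, 2, MISSING]], samples=["a", "b", "og"])
        out = polarize(t, "og")
        assert out.outgroup_missing[0]

    def test_idempotent_and_call_preserving_when_outgroup_homozygous(self):
        """Re-polarizing a polarized table is a no-op, and the underlying
        allele calls (dosage of the physical alt nucleotide) are unchanged."""
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (30, 4)).astype(np.int8)
        d[:, -1] = rng.choice([0, 2], 30)  # homozygous outgroup everywhere
        t = make_table(np.arange(1, 31) * 5, d, samples=["a", "b", "c", "og"])
        once = polarize(t, "og")
        twice = polarize(once, "og")
        np.testing.assert_array_equal(twice.dosage, once.dosage)
        np.testing.assert_array_equal(twice.alt, once.alt)
        # dosage of the nucleotide 'T' is invariant under recoding
        dos_t = np.where(once.alt == "T", once.dosage.T, 2 - once.dosage.T).T
        orig_t = np.where(t.alt == "T", t.dosage.T, 2 - t.dosage.T).T
        np.testing.assert_array_equal(dos_t, orig_t)


class TestAlleleFreqs:
    @pytest.mark.parametrize("dosages,members,expected", [
        ([[1]], ["s0"], 0.5),
        ([[2, 0]], ["s0", "s1"], 0.5),
        ([[2, MISSING, 1]], ["s0", "s1", "s2"], 0.75),
    ])
    def test_hand_counts(self, dosages, members, expected):
        t = make_table([10], dosages)
        assert allele_freqs(t, members)[0] == pytest.approx(expected)

    def test_all_missing_gives_nan(self):
        t = make_table([10], [[MISSING, MISSING]])
        assert np.isnan(allele_freqs(t, ["s0", "s1"])[0])

    def test_empty_members_raises(self):
        t = make_table([10], [[0]])
        with pytest.raises(IntrogrescanError):
            allele_freqs(t, [])
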