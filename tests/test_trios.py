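"""ABBA-BABA pattern sums, D, f4-ratio, jackknife and trio enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from introgrescan import (
    BlockSeries,
    SampleMap,
    allele_freqs,
    block_jackknife,
    bonferroni_filter,
    compute_trio,
    enumerate_and_orient,
    f4_ratio,
    pattern_sums,
    patterson_d,
    polarize,
    simulate_site_patterns,
)
from introgrescan.core import IntrogrescanError
from introgrescan.trios import TrioResult, site_patterns, split_p3_freqs

freq_arrays = hnp.arrays(np.float64, st.integers(1, 30),
                         elements=st.floats(0, 1, allow_nan=False))


class TestPatternSums:
    def test_pure_abba_site(self):
        bbaa, abba, baba = pattern_sums([0], [1], [1], [0])
        assert (abba, baba, bbaa) == (1.0, 0.0, 0.0)

    def test_hand_computed_three_sites(self):
        """Sums equal an explicit per-site loop at p=(0.2,0.8,0.6,0)."""
        p1, p2, p3, p4 = [0.2] * 3, [0.8] * 3, [0.6] * 3, [0.0] * 3
        exp_abba = exp_baba = exp_bbaa = 0.0
        for a, b, c, d in zip(p1, p2, p3, p4):
            exp_abba += (1 - a) * b * c * (1 - d) + a * (1 - b) * (1 - c) * d
            exp_baba += a * (1 - b) * c * (1 - d) + (1 - a) * b * (1 - c) * d
            exp_bbaa += a * b * (1 - c) * (1 - d) + (1 - a) * (1 - b) * c * d
        bbaa, abba, baba = pattern_sums(p1, p2, p3, p4)
        assert abba == pytest.approx(exp_abba)
        assert baba == pytest.approx(exp_baba)
        assert bbaa == pytest.approx(exp_bbaa)

    @settings(deadline=None)
    @given(freq_arrays, freq_arrays.map(lambda a: a))
    def test_p1_equals_p2_balances_patterns(self, p, p3):
        """With P1 == P2 site-wise, ABBA and BABA weights are equal."""
        n = min(len(p), len(p3))
        p, p3 = p[:n], p3[:n]
        p4 = np.zeros(n)
        _, abba, baba = pattern_sums(p, p, p3, p4)
        assert abba == pytest.approx(baba)

    @settings(deadline=None)
    @given(freq_arrays)
    def test_swapping_p1_p2_flips_abba_baba(self, p3):
        rng = np.random.default_rng(0)
        n = len(p3)
        p1, p2, p4 = rng.random(n), rng.random(n), rng.random(n)
        _, abba, baba = pattern_sums(p1, p2, p3, p4)
        _, abba2, baba2 = pattern_sums(p2, p1, p3, p4)
        assert abba2 == pytest.approx(baba)
        assert baba2 == pytest.approx(abba)
        d1, d2 = patterson_d(abba, baba), patterson_d(abba2, baba2)
        if not np.isnan(d1):
            assert d2 == pytest.approx(-d1)

    @pytest.mark.parametrize("fixed", [0.0, 1.0])
    def test_uninformative_fixed_site_neutral(self, fixed):
        """A site fixed (0 or 1) in all four populations carries no weight,
        so adding it changes no pattern sum and no statistic."""
        base = ([0.2, 0.7], [0.9, 0.1], [0.5, 0.5], [0.0, 0.3])
        with_extra = tuple(np.append(x, fixed) for x in base)
        s1 = pattern_sums(*base)
        s2 = pattern_sums(*with_extra)
        assert s1 == pytest.approx(s2)
        assert patterson_d(s1[1], s1[2]) == pytest.approx(patterson_d(s2[1], s2[2]))

    def test_bad_frequency_raises(self):
        with pytest.raises(IntrogrescanError):
            pattern_sums([1.2], [0], [0], [0])

    def test_missing_site_skipped(self):
        _, abba, _ = pattern_sums([0, np.nan], [1, 1], [1, 1], [0, 0])
        assert abba == 1.0


class TestPattersonD:
    @pytest.mark.parametrize("abba,baba,expected", [
        (30, 10, 0.5),
        (10, 10, 0.0),
    ])
    def test_arithmetic(self, abba, baba, expected):
        assert patterson_d(abba, baba) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        assert np.isnan(patterson_d(0.0, 0.0))


class TestF4Ratio:
    def test_p2_equals_p1_gives_zero(self):
        rng = np.random.default_rng(1)
        p1 = rng.random(50)
        p3 = rng.random(50)
        assert f4_ratio(p1, p1, p3, p3, np.zeros(50)) == pytest.approx(0.0)

    def test_full_replacement_gives_one(self):
        rng = np.random.default_rng(2)
        p1, p3 = rng.random(50), rng.random(50)
        assert f4_ratio(p1, p3, p3, p3, np.zeros(50)) == pytest.approx(1.0)

    def test_split_half_invariance(self, null_sim, null_roles):
        """Two random P3 splits give nearly identical estimates."""
        t, _ = null_sim
        f1 = allele_freqs(t, null_roles["P1"])
        f2 = allele_freqs(t, null_roles["P2"])
        f4 = allele_freqs(t, null_roles["outgroup"])
        idx = t.sample_indices(null_roles["P3"])
        ests = []
        for seed in (1, 2):
            p3a, p3b = split_p3_freqs(t.dosage[:, idx], np.random.default_rng(seed))
            ests.append(f4_ratio(f1, f2, p3a, p3b, f4))
        assert abs(ests[0] - ests[1]) < 0.02


class TestBlockJackknife:
    def test_identical_blocks_flagged(self):
        z, p, se = block_jackknife(BlockSeries([3.0, 3.0, 3.0], [1.0, 1.0, 1.0]))
        assert se == 0 and np.isinf(z) and p == 0

    def test_symmetric_blocks_give_zero_z(self):
        z, p, se = block_jackknife(BlockSeries([1.0, 3.0], [3.0, 1.0]))
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_independent_delete_one_formula(self):
        """Z agrees with a from-scratch reimplementation of the jackknife."""
        rng = np.random.default_rng(7)
        a = rng.uniform(5, 15, 20)
        b = rng.uniform(5, 15, 20)
        z, p, se = block_jackknife(BlockSeries(a, b))
        # independent oracle, scalar arithmetic only
        ta, tb = sum(a), sum(b)
        thetas = []
        for i in range(20):
            xa, xb = ta - a[i], tb - b[i]
            thetas.append((xa - xb) / (xa + xb))
        mean = sum(thetas) / 20
        var = (20 - 1) / 20 * sum((th - mean) ** 2 for th in thetas)
        oracle_z = ((ta - tb) / (ta + tb)) / var ** 0.5
        assert z == pytest.approx(oracle_z, rel=1e-12)

    def test_too_few_blocks_raises(self):
        with pytest.raises(IntrogrescanError):
            block_jackknife(BlockSeries([1.0], [1.0]))

    def test_block_sums_total_genome_sums(self):
        rng = np.random.default_rng(9)
        abba, baba = rng.random(1000), rng.random(1000)
        bs = BlockSeries.from_sites(abba, baba, m=20)
        assert bs.abba.sum() == pytest.approx(abba.sum())
        assert bs.baba.sum() == pytest.approx(baba.sum())


def _smap(p1, p2, p3):
    names = p1 + p2 + p3 + ["OG"]
    return SampleMap(sample=names, species={n: n for n in names},
                     group={n: n for n in names},
                     roles={"P1": set(p1), "P2": set(p2), "P3": set(p3),
                            "outgroup": {"OG"}})


class TestEnumerateAndOrient:
    def test_role_product(self):
        smap = _smap(["a", "b"], ["c", "d", "e"], ["f", "g"])
        assert len(enumerate_and_orient(smap)) == 2 * 3 * 2

    def test_overlapping_roles_raise(self):
        smap = _smap(["a"], ["c"], ["f"])
        smap.roles["P2"].add("a")
        with pytest.raises(IntrogrescanError):
            enumerate_and_orient(smap)

    def test_guide_tree_sister_pairs(self):
        """On ((A,B),(C,D)) exactly the sister-consistent trios emerge."""
        smap = _smap(["A"], ["B"], ["C"])
        trios = enumerate_and_orient(smap, guide_tree="((A,B),(C,D));")
        assert set(trios) == {("A", "B", "C"), ("A", "B", "D"),
                              ("C", "D", "A"), ("C", "D", "B")}


class TestBonferroni:
    def _result(self, p, d=0.1):
        return TrioResult("a", "b", "c", 1, 1, 1, d, 1.0, p, 0.0)

    def test_threshold_arithmetic(self):
        results = [self._result(0.5)] * 1000
        _, thr = bonferroni_filter(results, alpha=0.05)
        assert thr == pytest.approx(5e-5)

    def test_none_significant(self):
        sig, _ = bonferroni_filter([self._result(0.9)] * 10)
        assert sig == []

    def test_matches_hand_filtering(self):
        ps = [1e-6, 0.2, 1e-3, 0.04, 1e-9]
        results = [self._result(p, d=(-1) ** i * 0.1) for i, p in enumerate(ps)]
        sig, thr = bonferroni_filter(results, alpha=0.05)
        expected = [r for r in results if r.p < 0.05 / 5]
        assert [r for r, _ in sig] == expected
        assert {tag for r, tag in sig} <= {"positive", "negative"}


class TestOnSimulatedData:
    def test_null_d_within_4_se(self, null_sim, null_roles, toy_demog):
        """Without gene flow, genome-wide D is within 4 jackknife SEs of 0."""
        t, _ = null_sim
        members = {k: v for k, v in null_roles.items()}
        members["O_0"] = ["O_0"]
        r = compute_trio(t, {**members, "P1": members["P1"], "P2": members["P2"],
                             "P3": members["P3"]},
                         "P1", "P2", "P3", "O_0")
        assert abs(r.z) < 4

    def test_pulse_gives_significant_positive_d(self, toy_demog):
        """A recent 20% pulse P3 -> P2 drives D strongly positive."""
        import dataclasses

        from introgrescan import Pulse

        d = dataclasses.replace(toy_demog, pulse=Pulse(fraction=0.2))
        t, _ = simulate_site_patterns(d, 8000, seed=7)
        t = polarize(t, "O_0")
        members = {"P1": ["P1_0", "P1_1"], "P2": ["P2_0", "P2_1"],
                   "P3": ["P3_0", "P3_1"], "O_0": ["O_0"]}
        r = compute_trio(t, members, "P1", "P2", "P3", "O_0")
        assert r.d > 0
        assert r.z > 3
        assert r.p < 0.01
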