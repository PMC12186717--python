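"""VCF input/output, site-quality filtering, inversion masking and
outgroup polarization.

The filter battery mirrors a conservative short-read joint-calling QC
scheme: overall mapping quality, MQ0 fraction, strand mapping-quality bias,
excess heterozygosity, per-site missingness, abnormally high total depth,
heterozygote allele-balance, and a proximity rule that discards sites lying
between two nearby failing sites.  All rules act on annotations carried in
the VCF (INFO tags and FORMAT allele depths); nothing is recomputed from
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import (
    ANNO_COLUMNS,
    MISSING,
    IntrogrescanError,
    MalformedRecordError,
    RegionMask,
    SampleNotFoundError,
    SiteTable,
)

#: INFO tags written/read for per-site annotations
_INFO_TAGS = {
    "MQ": ("MQ", "Float", "RMS mapping quality"),
    "MQ0F": ("MQ0F", "Float", "Fraction of reads with mapping quality zero"),
    "STRAND_P": ("STRAND_P", "Float", "Forward/reverse strand MQ bias p-value"),
    "EXHET_P": ("EXHET_P", "Float", "Excess heterozygosity p-value"),
    "DP": ("DP", "Integer", "Total read depth across samples"),
}


# --------------------------------------------------------------------- read

def read_vcf(path: str | Path, samples: list[str] | None = None) -> SiteTable:
    """Read a (possibly gzipped) VCF into a :class:`SiteTable`.

    Only biallelic SNP records are kept; multiallelic records and indels are
    dropped and counted.  Missing genotypes are preserved as ``-1``.

    Parameters
    ----------
    path
        VCF path.
    samples
        Optional sample subset (order respected).  A requested sample absent
        from the header raises :class:`SampleNotFoundError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise SampleNotFoundError(f"samples not in VCF header: {missing}")
        vcf = VCF(str(path), gts012=True, samples=list(samples))
    names = list(vcf.samples)

    chrom, pos, ref, alt = [], [], [], []
    dosage_rows, ad_ref_rows, ad_alt_rows, anno_rows = [], [], [], []
    n_dropped = 0
    have_ad = False
    for rec in vcf:
        try:
            if len(rec.ALT) != 1 or not rec.is_snp:
                n_dropped += 1
                continue
            chrom.append(rec.CHROM)
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(rec.ALT[0])
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = np.asarray(rec.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            dosage_rows.append(gt)
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None and ad.shape[1] >= 2:
                have_ad = True
                ad = ad.astype(np.int32)
                ad[ad < 0] = -1
                ad_ref_rows.append(ad[:, 0])
                ad_alt_rows.append(ad[:, 1])
            else:
                ad_ref_rows.append(np.full(len(names), -1, dtype=np.int32))
                ad_alt_rows.append(np.full(len(names), -1, dtype=np.int32))
            anno_rows.append([rec.INFO.get(tag) for tag in ANNO_COLUMNS])
        except SampleNotFoundError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise MalformedRecordError(
                f"cannot parse record at {rec.CHROM}:{rec.POS}: {exc}"
            ) from exc

    n = len(pos)
    anno = pd.DataFrame(anno_rows, columns=list(ANNO_COLUMNS), dtype=float) if n else None
    t = SiteTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=np.array(dosage_rows, dtype=np.int8) if n else np.zeros((0, len(names)), np.int8),
        samples=names,
        anno=anno,
        ad_ref=np.array(ad_ref_rows, dtype=np.int32) if (n and have_ad) else None,
        ad_alt=np.array(ad_alt_rows, dtype=np.int32) if (n and have_ad) else None,
    )
    t.n_dropped_non_biallelic = n_dropped  # type: ignore[attr-defined]
    t.validate()
    return t


# -------------------------------------------------------------------- write

def write_vcf(t: SiteTable, path: str | Path) -> None:
    """Write a :class:`SiteTable` as an uncompressed VCF with GT:AD."""
    lines = ["##fileformat=VCFv4.2"]
    for c in t.chromosomes():
        lines.append(f"##contig=<ID={c}>")
    for tag, (_, typ, desc) in _INFO_TAGS.items():
        lines.append(f'##INFO=<ID={tag},Number=1,Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(t.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    have_ad = t.ad_ref is not None
    for i in range(t.n_sites):
        if t.anno is not None:
            row = t.anno.iloc[i]
            parts = []
            for tag in ANNO_COLUMNS:
                v = row[tag]
                if pd.notna(v):
                    parts.append(f"{tag}={int(v)}" if tag == "DP" else f"{tag}={v:g}")
            info = ";".join(parts) or "."
        else:
            info = "."
        cells = []
        for j in range(t.n_samples):
            g = gt_str[int(t.dosage[i, j])]
            if have_ad:
                ar, aa = int(t.ad_ref[i, j]), int(t.ad_alt[i, j])
                ad = f"{ar},{aa}" if ar >= 0 else ".,."
                cells.append(f"{g}:{ad}")
            else:
                cells.append(g)
        fmt = "GT:AD" if have_ad else "GT"
        lines.append(
            f"{t.chrom[i]}\t{t.pos[i]}\t.\t{t.ref[i]}\t{t.alt[i]}\t.\t.\t{info}\t{fmt}\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ filters

@dataclass
class FilterParams:
    """Thresholds for the site-filter battery.

    Defaults follow the conservative joint-calling scheme this pipeline
    reproduces: ``MQ >= 50``, MQ0 fraction <= 0.10, strand-MQ bias
    ``p >= 0.001``, excess-het ``p >= 0.2``, missingness <= 0.20, total depth
    no more than 1.5 SD above the across-site mean, heterozygote
    allele-balance binomial PHRED <= 20, and removal of sites lying between
    two failing sites <= 10 bp apart.  Any rule can be disabled with
    ``None``.
    """

    mq_min: float | None = 50.0
    mq0f_max: float | None = 0.10
    strand_p_min: float | None = 0.001
    exhet_p_min: float | None = 0.2
    miss_max: float | None = 0.20
    depth_sd: float | None = 1.5
    depth_cutoff: float | None = None  # explicit cutoff overrides depth_sd
    ab_phred_max: float | None = 20.0
    ab_rule: str = "any"  # "any" or "majority" of het genotypes failing
    proximity_bp: int | None = 10


@dataclass
class FilterLog:
    """Per-rule removal counts and positions, plus resolved thresholds."""

    removed: dict = field(default_factory=dict)  # rule -> list[(chrom,pos)]
    skipped_rules: list = field(default_factory=list)
    depth_cutoff: float | None = None

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.removed.items()}

    def n_removed_unique(self) -> int:
        return len({cp for v in self.removed.values() for cp in v})

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, c, p) for rule, v in self.removed.items() for c, p in v]
        return pd.DataFrame(rows, columns=["rule", "chrom", "pos"])


def het_allele_balance_phred(ad_ref: np.ndarray, ad_alt: np.ndarray) -> np.ndarray:
    """PHRED-scaled two-sided binomial(0.5) allele-balance score.

    For read depths (r, a) of a heterozygous genotype the score is
    ``-10*log10(p)`` with p the exact two-sided binomial probability of a
    deviation at least as large as ``|r - (r+a)/2|`` at rate 0.5.  Balanced
    depths give 0; strongly skewed depths give large scores.
    """
    r = np.asarray(ad_ref, dtype=np.int64)
    a = np.asarray(ad_alt, dtype=np.int64)
    if (r < 0).any() or (a < 0).any():
        raise IntrogrescanError("negative allele depths")
    n = r + a
    m = np.minimum(r, a)
    with np.errstate(divide="ignore"):
        p = np.minimum(1.0, 2.0 * binom.cdf(m, np.maximum(n, 1), 0.5))
        p[n == 0] = 1.0
        return -10.0 * np.log10(p)


def apply_site_filters(t: SiteTable, params: FilterParams | None = None):
    """Apply the quality-filter battery; return (filtered table, log).

    Rules whose annotations are absent are skipped and recorded in
    ``log.skipped_rules``.  The depth cutoff, when data-driven
    (``depth_cutoff is None``), is estimated once from the *input* table as
    ``mean + depth_sd * SD`` of per-site total depth and recorded in the log;
    re-running with that recorded cutoff reproduces the same decisions.
    After the per-site rules, any passing site lying between two removed
    sites no more than ``proximity_bp`` apart on the same chromosome is also
    removed (single pass over the originally failing sites).
    """
    params = params or FilterParams()
    log = FilterLog()
    n = t.n_sites
    fail = np.zeros(n, dtype=bool)
    anno = t.anno

    def col(name: str) -> np.ndarray | None:
        if anno is None or name not in anno.columns:
            return None
        v = anno[name].to_numpy(dtype=float)
        return v

    def record(rule: str, mask: np.ndarray) -> None:
        log.removed[rule] = [(str(t.chrom[i]), int(t.pos[i])) for i in np.flatnonzero(mask)]

    def apply_rule(rule: str, name: str, cmp) -> None:
        v = col(name)
        if v is None:
            log.skipped_rules.append(rule)
            return
        with np.errstate(invalid="ignore"):
            mask = np.where(np.isnan(v), False, cmp(v))
        record(rule, mask)
        nonlocal fail
        fail |= mask

    if params.mq_min is not None:
        apply_rule("MQ", "MQ", lambda v: v < params.mq_min)
    if params.mq0f_max is not None:
        apply_rule("MQ0F", "MQ0F", lambda v: v > params.mq0f_max)
    if params.strand_p_min is not None:
        apply_rule("STRAND_P", "STRAND_P", lambda v: v < params.strand_p_min)
    if params.exhet_p_min is not None:
        apply_rule("EXHET_P", "EXHET_P", lambda v: v < params.exhet_p_min)

    if params.miss_max is not None:
        mask = t.missing_fraction() > params.miss_max
        record("MISSING", mask)
        fail |= mask

    if params.depth_cutoff is not None or params.depth_sd is not None:
        dp = col("DP")
        if dp is None:
            log.skipped_rules.append("DEPTH")
        else:
            if (dp[~np.isnan(dp)] < 0).any():
                raise IntrogrescanError("negative depths")
            cutoff = params.depth_cutoff
            if cutoff is None:
                ok = ~np.isnan(dp)
                cutoff = float(dp[ok].mean() + params.depth_sd * dp[ok].std())
            log.depth_cutoff = cutoff
            mask = np.where(np.isnan(dp), False, dp > cutoff)
            record("DEPTH", mask)
            fail |= mask

    if params.ab_phred_max is not None:
        if t.ad_ref is None or t.ad_alt is None:
            log.skipped_rules.append("ALLELE_BALANCE")
        else:
            het = t.dosage == 1
            usable = het & (t.ad_ref >= 0) & (t.ad_alt >= 0)
            phred = np.zeros_like(t.ad_ref, dtype=float)
            if usable.any():
                phred[usable] = het_allele_balance_phred(
                    t.ad_ref[usable], t.ad_alt[usable]
                )
            failing = usable & (phred > params.ab_phred_max)
            if params.ab_rule == "any":
                mask = failing.any(axis=1)
            elif params.ab_rule == "majority":
                n_het = usable.sum(axis=1)
                mask = (n_het > 0) & (failing.sum(axis=1) * 2 > n_het)
            else:
                raise IntrogrescanError(f"unknown ab_rule {params.ab_rule!r}")
            record("ALLELE_BALANCE", mask)
            fail |= mask

    # proximity rule: passing sites bracketed by two nearby failing sites
    if params.proximity_bp is not None and fail.any():
        prox = np.zeros(n, dtype=bool)
        for c in t.chromosomes():
            on_c = np.flatnonzero(t.chrom.astype(str) == c)
            bad = on_c[fail[on_c]]
            for i, j in zip(bad[:-1], bad[1:]):
                if t.pos[j] - t.pos[i] <= params.proximity_bp:
                    prox[i + 1:j] = True
        prox &= ~fail
        record("PROXIMITY", prox)
        fail |= prox

    return t.take_sites(~fail), log


def mask_regions(t: SiteTable, m: RegionMask) -> SiteTable:
    """Drop all sites inside the (1-based inclusive) mask intervals."""
    if not m.intervals:
        return t.take_sites(np.ones(t.n_sites, dtype=bool))
    inside = m.normalized().contains(t.chrom, t.pos)
    return t.take_sites(~inside)


# -------------------------------------------------------------- polarization

def polarize(t: SiteTable, outgroup: str) -> SiteTable:
    """Recode dosages so they count derived alleles, using ``outgroup`` as
    the ancestral-state carrier.

    Sites where the outgroup is homozygous alt are flipped (``d -> 2 - d``);
    homozygous ref sites are unchanged.  Sites where the outgroup is
    heterozygous or missing are kept but flagged; downstream statistics use
    the outgroup frequency (0.5) for het sites and must exclude
    outgroup-missing sites.
    """
    k = t.sample_index(outgroup)
    og = t.dosage[:, k]
    out = t.take_sites(np.ones(t.n_sites, dtype=bool))
    flip = og == 2
    d = out.dosage
    sub = d[flip]
    sub[sub >= 0] = 2 - sub[sub >= 0]
    d[flip] = sub
    ref, alt = out.ref.copy(), out.alt.copy()
    ref[flip], alt[flip] = out.alt[flip], out.ref[flip]
    out.ref, out.alt = ref, alt
    if out.ad_ref is not None:
        ar = out.ad_ref.copy()
        aa = out.ad_alt.copy()
        ar[flip], aa[flip] = out.ad_alt[flip], out.ad_ref[flip]
        out.ad_ref, out.ad_alt = ar, aa
    out.polarized = True
    out.outgroup_het = og == 1
    out.outgroup_missing = og == MISSING
    return out


def allele_freqs(t: SiteTable, members: list[str]) -> np.ndarray:
    """Per-site alt/derived allele frequency over a pooled sample set.

    ``freq = sum(dosage) / (2 * n_non_missing)``; sites where every member
    is missing get ``nan``.
    """
    if not members:
        raise IntrogrescanError("empty member set")
    idx = t.sample_indices(members)
    d = t.dosage[:, idx].astype(float)
    obs = d != MISSING
    d[~obs] = 0.0
    denom = 2.0 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = d.sum(axis=1) / denom
    f[denom == 0] = np.nan
    return f
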