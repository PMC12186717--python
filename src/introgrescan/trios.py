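"""Genome-wide ABBA-BABA statistics: pattern sums, Patterson's D, the
f4-ratio admixture estimate, block-jackknife significance, trio
enumeration/orientation and Bonferroni filtering.

All statistics are computed from per-site derived-allele frequencies
p1, p2, p3, p4 of the four populations of an (((P1,P2),P3),O) tree.  With
frequencies, the discordant pattern "counts" are weighted sums:

    ABBA = (1-p1) p2 p3 (1-p4) + p1 (1-p2) (1-p3) p4
    BABA = p1 (1-p2) p3 (1-p4) + (1-p1) p2 (1-p3) p4
    BBAA = p1 p2 (1-p3) (1-p4) + (1-p1) (1-p2) p3 p4

and D = (ABBA - BABA) / (ABBA + BABA).  A positive D marks excess
derived-allele sharing between P2 and P3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import IntrogrescanError, SampleMap


# ------------------------------------------------------------- pattern sums

def _check_freqs(*fs):
    n = {len(f) for f in fs}
    if len(n) != 1:
        raise IntrogrescanError("frequency sequences of unequal length")
    for f in fs:
        v = np.asarray(f, dtype=float)
        ok = ~np.isnan(v)
        if ((v[ok] < 0) | (v[ok] > 1)).any():
            raise IntrogrescanError("frequency outside [0, 1]")


def site_patterns(p1, p2, p3, p4):
    """Per-site ABBA/BABA/BBAA weights; rows with any missing freq are NaN."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    _check_freqs(p1, p2, p3, p4)
    abba = (1 - p1) * p2 * p3 * (1 - p4) + p1 * (1 - p2) * (1 - p3) * p4
    baba = p1 * (1 - p2) * p3 * (1 - p4) + (1 - p1) * p2 * (1 - p3) * p4
    bbaa = p1 * p2 * (1 - p3) * (1 - p4) + (1 - p1) * (1 - p2) * p3 * p4
    return abba, baba, bbaa


def pattern_sums(p1, p2, p3, p4):
    """Genome-wide (nBBAA, nABBA, nBABA); sites with missing freqs skipped."""
    abba, baba, bbaa = site_patterns(p1, p2, p3, p4)
    return (float(np.nansum(bbaa)), float(np.nansum(abba)), float(np.nansum(baba)))


def patterson_d(n_abba: float, n_baba: float) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when the denominator is 0."""
    denom = n_abba + n_baba
    if denom == 0:
        return float("nan")
    return (n_abba - n_baba) / denom


# ----------------------------------------------------------------- f4-ratio

def f4_ratio(p1, p2, p3a, p3b, p4) -> float:
    """Admixture-fraction estimate from two f4 statistics.

    The P3 population is split into halves a and b;

        f4-ratio = sum (p1 - p2)(p3a - p4) / sum (p1 - p3b)(p3a - p4)

    equals 0 when P2 is indistinguishable from P1 and 1 on complete
    replacement of P2 by the donor.  NaN when the denominator vanishes.
    """
    p1, p2, p3a, p3b, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3a, p3b, p4))
    _check_freqs(p1, p2, p3a, p3b, p4)
    num = np.nansum((p1 - p2) * (p3a - p4))
    den = np.nansum((p1 - p3b) * (p3a - p4))
    if den == 0:
        return float("nan")
    return float(num / den)


def split_p3_freqs(dosage: np.ndarray, rng: np.random.Generator):
    """Randomly split P3 chromosomes into halves a/b at every site.

    ``dosage`` is the (n_sites, n_p3_samples) derived-dosage submatrix.  Per
    site, the non-missing chromosomes (2 per genotype) carry ``k`` derived
    alleles out of ``n``; a hypergeometric draw assigns ``n//2`` of them to
    half a, the rest to half b -- the standard device when phased haplotypes
    are not tracked.  Returns (p3a, p3b) frequency arrays.
    """
    d = dosage.astype(float)
    obs = d >= 0
    d[~obs] = 0.0
    n = 2 * obs.sum(axis=1)
    k = d.sum(axis=1)
    na = n // 2
    p3a = np.full(len(d), np.nan)
    p3b = np.full(len(d), np.nan)
    ok = n >= 2
    ka = rng.hypergeometric(k[ok].astype(np.int64), (n[ok] - k[ok]).astype(np.int64),
                            na[ok].astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        p3a[ok] = ka / na[ok]
        p3b[ok] = (k[ok] - ka) / (n[ok] - na[ok])
    return p3a, p3b


# ------------------------------------------------------------ block jackknife

@dataclass
class BlockSeries:
    """Per-block ABBA/BABA sums over m contiguous genome blocks."""

    abba: np.ndarray
    baba: np.ndarray

    def __post_init__(self):
        self.abba = np.asarray(self.abba, dtype=float)
        self.baba = np.asarray(self.baba, dtype=float)
        if len(self.abba) != len(self.baba):
            raise IntrogrescanError("block series length mismatch")

    @property
    def m(self) -> int:
        return len(self.abba)

    @classmethod
    def from_sites(cls, abba: np.ndarray, baba: np.ndarray, m: int = 20) -> "BlockSeries":
        """Split genome-ordered per-site weights into m contiguous blocks of
        (near-)equal site count; sites with missing weights contribute 0."""
        abba = np.nan_to_num(np.asarray(abba, dtype=float))
        baba = np.nan_to_num(np.asarray(baba, dtype=float))
        edges = np.linspace(0, len(abba), m + 1).round().astype(int)
        a = np.array([abba[edges[i]:edges[i + 1]].sum() for i in range(m)])
        b = np.array([baba[edges[i]:edges[i + 1]].sum() for i in range(m)])
        return cls(a, b)


def block_jackknife(b: BlockSeries):
    """Delete-one-block jackknife for D; returns (Z, p, SE).

    The delete-one estimates are D computed from the genome-wide sums minus
    one block; SE is the standard delete-one jackknife standard error
    ``sqrt((m-1)/m * sum (theta_i - mean)^2)`` and ``Z = D / SE`` with a
    two-sided normal p-value.  Identical block estimates give SE = 0 and are
    flagged with an infinite Z (p = 0 unless D itself is 0).
    """
    if b.m < 2:
        raise IntrogrescanError("need at least 2 blocks")
    ta, tb = b.abba.sum(), b.baba.sum()
    if ta + tb == 0:
        return float("nan"), float("nan"), float("nan")
    d_full = (ta - tb) / (ta + tb)
    da = ta - b.abba
    db = tb - b.baba
    denom = da + db
    if (denom == 0).any():
        raise IntrogrescanError("empty jackknife block")
    theta = (da - db) / denom
    se = float(np.sqrt((b.m - 1) / b.m * ((theta - theta.mean()) ** 2).sum()))
    if se == 0:
        if d_full == 0:
            return 0.0, 1.0, 0.0
        return float(np.sign(d_full)) * float("inf"), 0.0, 0.0
    z = d_full / se
    p = 2 * norm.sf(abs(z))
    return float(z), float(p), se


# -------------------------------------------------------------- trio results

@dataclass
class TrioResult:
    """One ABBA-BABA test for an ordered trio (P1, P2, P3)."""

    p1: str
    p2: str
    p3: str
    n_bbaa: float
    n_abba: float
    n_baba: float
    d: float
    z: float
    p: float
    f4ratio: float


def compute_trio(t, members: dict, p1: str, p2: str, p3: str, outgroup,
                 n_blocks: int = 20, rng: np.random.Generator | None = None) -> TrioResult:
    """Full statistics for one trio on a polarized :class:`SiteTable`.

    ``members`` maps a species/group label to its sample list; ``outgroup``
    is the label of the ancestral-state carrier.  Sites where the outgroup is
    missing are excluded.
    """
    from .genotype_io import allele_freqs

    rng = rng or np.random.default_rng(0)
    f1 = allele_freqs(t, members[p1])
    f2 = allele_freqs(t, members[p2])
    f3 = allele_freqs(t, members[p3])
    f4 = allele_freqs(t, members[outgroup] if outgroup in members else [outgroup])
    abba, baba, bbaa = site_patterns(f1, f2, f3, f4)
    n_bbaa, n_abba, n_baba = (float(np.nansum(x)) for x in (bbaa, abba, baba))
    d = patterson_d(n_abba, n_baba)
    z, p, _ = block_jackknife(BlockSeries.from_sites(abba, baba, m=n_blocks))
    idx = t.sample_indices(members[p3])
    p3a, p3b = split_p3_freqs(t.dosage[:, idx], rng)
    fr = f4_ratio(f1, f2, p3a, p3b, f4)
    return TrioResult(p1, p2, p3, n_bbaa, n_abba, n_baba, d, z, p, fr)


# ---------------------------------------------------- enumeration / filtering

def enumerate_and_orient(smap: SampleMap, guide_tree: str | None = None) -> list:
    """Ordered (P1, P2, P3) trios consistent with the guide topology.

    In *role* mode every combination from the declared P1/P2/P3 role sets is
    emitted; orientation is fixed by the roles (so the sign of D keeps its
    meaning) and a species occurring in two role sets is an error.  In
    *guide-tree* mode (``guide_tree`` = newick string or file), all species
    triples whose (P1, P2) pair is sister relative to P3 on the tree are
    emitted once, with the sister pair in lexicographic order.
    """
    if guide_tree is None:
        roles = smap.roles
        for a, b in itertools.combinations(("P1", "P2", "P3"), 2):
            both = roles.get(a, set()) & roles.get(b, set())
            if both:
                raise IntrogrescanError(f"species in both {a} and {b} role sets: {sorted(both)}")
        known = set(smap.all_species())
        out = []
        for sp in ("P1", "P2", "P3"):
            for s in sorted(roles.get(sp, set()) - known):
                import warnings

                warnings.warn(f"role {sp} species {s!r} absent from sample map; skipped")
        p1s = sorted(roles.get("P1", set()) & known)
        p2s = sorted(roles.get("P2", set()) & known)
        p3s = sorted(roles.get("P3", set()) & known)
        return [(a, b, c) for a in p1s for b in p2s for c in p3s]

    import dendropy

    # the guide tree is a rooted species topology; prevent derooting
    if "(" in guide_tree:
        tree = dendropy.Tree.get(data=guide_tree, schema="newick",
                                 rooting="force-rooted")
    else:
        tree = dendropy.Tree.get(path=guide_tree, schema="newick",
                                 rooting="force-rooted")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    trios = []
    for a, b, c in itertools.combinations(sorted(labels), 3):
        for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
            mrca_xy = tree.mrca(taxon_labels=[x, y])
            mrca_xyz = tree.mrca(taxon_labels=[x, y, z])
            if mrca_xy is not mrca_xyz:
                trios.append((x, y, z))
    return trios


def bonferroni_filter(results: list, alpha: float = 0.05):
    """Bonferroni-significant trios: p < alpha / n_trios.

    Returns ``(significant, threshold)`` where each selected trio is tagged
    with the sign of its D ('positive'/'negative').
    """
    if not results:
        raise IntrogrescanError("no trio results to filter")
    threshold = alpha / len(results)
    sig = [(r, "positive" if r.d > 0 else "negative")
           for r in results if r.p < threshold]
    return sig, threshold
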