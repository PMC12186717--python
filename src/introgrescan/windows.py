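"""Windowed fdM introgression scan, candidate selection and
adjacency-enrichment statistics.

fdM is a dynamically normalised window statistic bounded in [-1, 1]: the
numerator is the ABBA - BABA imbalance summed over the window's sites and
the denominator is the same imbalance computed after substituting, per site,
the higher derived-allele frequency of the tested donor pair for both of its
members ({P2, P3} for positive sharing, {P1, P3} for negative sharing).
Positive fdM marks excess allele sharing between P3 and P2, negative between
P3 and P1.

Candidates for introgression are windows whose fdM exceeds the magnitude of
the negative-tail quantile: under the no-gene-flow null fdM is symmetric
around zero, so the negative tail gauges how far positive values wander by
chance.  Adjacency statistics then ask whether candidates clump along the
genome more than independent labels would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import IntrogrescanError, SiteTable
from .genotype_io import allele_freqs
from .trios import site_patterns


@dataclass
class WindowStat:
    """One non-overlapping window of ``n_snps`` informative SNPs."""

    chrom: str
    start: int
    end: int
    n_snps: int
    fdm: float

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class CandidateReport:
    """Candidate-window selection summary."""

    threshold: float
    candidate_ids: np.ndarray  # indices into the window list
    n_windows: int
    all_positive: bool = False

    @property
    def k(self) -> int:
        return len(self.candidate_ids)

    @property
    def percent(self) -> float:
        return 100.0 * self.k / self.n_windows if self.n_windows else float("nan")


@dataclass
class AdjacencyReport:
    """Observed vs expected genome-adjacency of candidate windows."""

    observed: int
    expected: float
    deviation: float
    run_lengths: dict = field(default_factory=dict)  # run length (>=2) -> count


# ----------------------------------------------------------------- fdM scan

def fdm_value(p1, p2, p3, p4):
    """fdM for one window given aligned frequency arrays (NaN rows skipped)."""
    abba, baba, _ = site_patterns(p1, p2, p3, p4)
    num = np.nansum(abba - baba)
    if num >= 0:
        pd23 = np.maximum(p2, p3)
        a, b, _ = site_patterns(p1, pd23, pd23, p4)
        den = np.nansum(a - b)
    else:
        pd13 = np.maximum(p1, p3)
        a, b, _ = site_patterns(pd13, p2, pd13, p4)
        den = -np.nansum(a - b)
    if den == 0:
        return 0.0 if num == 0 else float("nan")
    return float(num / den)


def informative_sites(t: SiteTable, roles: dict) -> np.ndarray:
    """Indices of sites usable by the scan: all four frequencies defined and
    p1, p2, p3 not all equal (sites contributing nothing are skipped)."""
    f = {r: allele_freqs(t, roles[r]) for r in ("P1", "P2", "P3", "outgroup")}
    ok = np.ones(t.n_sites, dtype=bool)
    for v in f.values():
        ok &= ~np.isnan(v)
    informative = ~((f["P1"] == f["P2"]) & (f["P2"] == f["P3"]))
    return np.flatnonzero(ok & informative), f


def fdm_windows(t: SiteTable, roles: dict, window_snps: int = 50) -> list:
    """Non-overlapping ``window_snps``-SNP fdM windows per chromosome.

    ``roles`` maps 'P1'/'P2'/'P3'/'outgroup' to sample lists (groups pooled
    into single test "species").  Windows advance by ``window_snps``
    informative SNPs; the trailing partial window of each chromosome is
    dropped.  Start/end are the positions of the first/last constituent SNP.
    """
    idx, f = informative_sites(t, roles)
    out: list[WindowStat] = []
    chrom = t.chrom.astype(str)
    for c in t.chromosomes():
        on_c = idx[chrom[idx] == c]
        n_full = len(on_c) // window_snps
        for w in range(n_full):
            sl = on_c[w * window_snps:(w + 1) * window_snps]
            val = fdm_value(f["P1"][sl], f["P2"][sl], f["P3"][sl], f["outgroup"][sl])
            out.append(WindowStat(chrom=c, start=int(t.pos[sl[0]]),
                                  end=int(t.pos[sl[-1]]), n_snps=window_snps, fdm=val))
    return out


def drop_oversize(windows: list, max_bp: int = 20_000) -> list:
    """Remove windows spanning more than ``max_bp`` (strict inequality)."""
    return [w for w in windows if w.span_bp <= max_bp]


# ---------------------------------------------------------------- candidates

def candidate_threshold(values, q: float = 0.005):
    """Positive-candidate threshold from the negative-tail quantile.

    ``threshold = |quantile(values, q)|`` with linear interpolation between
    order statistics; candidates are values strictly above it.  If the
    q-quantile is not negative the threshold is 0 and a warning is issued.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise IntrogrescanError("no fdM values")
    qv = float(np.quantile(v, q))
    all_positive = qv > 0
    if all_positive:
        warnings.warn("negative-tail quantile is positive; threshold set to 0")
        threshold = 0.0
    else:
        threshold = abs(qv)
    return threshold, all_positive


def select_candidates(windows: list, q: float = 0.005) -> CandidateReport:
    """Candidate windows: fdM strictly above the negative-tail threshold."""
    vals = np.array([w.fdm for w in windows], dtype=float)
    threshold, all_positive = candidate_threshold(vals, q)
    with np.errstate(invalid="ignore"):
        ids = np.flatnonzero(vals > threshold)
    return CandidateReport(threshold=threshold, candidate_ids=ids,
                           n_windows=len(windows), all_positive=all_positive)


# -------------------------------------------------------------- diagnostics

def ks_vs_normal(values):
    """One-sample KS test of fdM values against a normal distribution.

    Values are standardised by their sample mean/SD and compared with the
    standard normal; the estimation of the reference parameters makes the
    test mildly anticonservative, which is accepted rather than corrected.
    Returns ``(D_KS, p, mean, sd, skewness)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 10:
        raise IntrogrescanError("need at least 10 values for the KS diagnostic")
    sd = v.std(ddof=1)
    if sd == 0:
        raise IntrogrescanError("zero variance")
    z = (v - v.mean()) / sd
    res = stats.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue), float(v.mean()), float(sd), float(stats.skew(v))


# ---------------------------------------------------------------- adjacency

def expected_adjacent(n_windows: int, k_candidates: int) -> float:
    """Expected count of candidate windows adjacent to another candidate
    under independent placement: ``(N - 1) * (k / N)^2 * 2``."""
    if n_windows <= 0:
        raise IntrogrescanError("no windows")
    return (n_windows - 1) * (k_candidates / n_windows) ** 2 * 2


def adjacency_stats(report: CandidateReport, windows: list) -> AdjacencyReport:
    """Observed/expected adjacency of candidate windows and run lengths.

    Adjacency means consecutive in the genome-ordered window list *within a
    chromosome*.  ``observed`` counts candidate windows immediately preceded
    or followed by another candidate; the run-length spectrum counts maximal
    candidate runs of each length >= 2 (a run of length 8 counts once at 8),
    so ``observed`` equals the sum of run length x count over the spectrum.
    """
    n = len(windows)
    k = report.k
    is_cand = np.zeros(n, dtype=bool)
    is_cand[report.candidate_ids] = True
    observed = 0
    runs: dict[int, int] = {}
    i = 0
    while i < n:
        if not is_cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_cand[j + 1] and windows[j + 1].chrom == windows[j].chrom:
            j += 1
        run_len = j - i + 1
        if run_len >= 2:
            observed += run_len
            runs[run_len] = runs.get(run_len, 0) + 1
        i = j + 1
    expected = expected_adjacent(n, k)
    deviation = observed / expected if expected > 0 else float("nan")
    return AdjacencyReport(observed=observed, expected=expected,
                           deviation=deviation, run_lengths=runs)
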