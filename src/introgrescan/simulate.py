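"""Coalescent synthetic data with known introgression and planted QC failures.

Two generation modes cover the two kinds of statistics downstream:

* :func:`simulate_site_patterns` draws each SNP from an *independent*
  coalescent genealogy of a (((P1,P2),P3),O) demography with an optional
  admixture pulse P3 -> P2.  Genealogies are accepted with probability
  proportional to their total branch length, so emitted sites follow the
  exact distribution of a randomly chosen segregating site on an infinitely
  large unlinked genome; an implied "accessible genome" length is recorded so
  per-site rates (heterozygosity, d_xy) are calibrated to the mutation rate.

* :func:`simulate_tracts` produces linked data for the window scan: donor
  ancestry tracts (Poisson number, exponential lengths) are planted on
  recipient haplotypes and, at every site inside a tract, the recipient
  haplotype's allele is copied from an auxiliary donor-population haplotype
  simulated alongside.  Site genealogies are therefore exactly those of a
  no-gene-flow model conditional on the local ancestry, and the truth record
  lists every tract.

:func:`plant_filter_failures` decorates clean annotations with violations of
exactly one named filter rule per chosen site.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, IntrogrescanError, SampleMap, SiteTable

_POPS = ("P1", "P2", "P3", "O")


@dataclass
class Pulse:
    """A single admixture pulse donor -> recipient at ``time`` generations."""

    donor: str = "P3"
    recipient: str = "P2"
    time: float = 1.0e5
    fraction: float = 0.0


@dataclass
class Demography:
    """A (((P1,P2),P3),O) demography with an optional P3 -> P2 pulse.

    Defaults are scaled to haplochromine cichlid heterozygosity: with
    ``ne = 1.43e5`` and ``mu = 3.5e-9`` per generation the stationary
    per-site heterozygosity is ``4*Ne*mu ~ 0.002``.  Split times are in
    generations before present; the toy defaults (0.3, 0.6 and 2 Myr of
    generations) sit at 1-2 coalescent units so that incomplete lineage
    sorting -- the raw material of the ABBA-BABA statistics -- is common,
    with the outgroup well outside the ingroup coalescences.  ``n_chrom`` chromosomes support the
    chromosome-delete jackknife; ``chrom_length`` and ``mean_tract_bp``
    parameterise the linked tract mode.
    """

    samples: dict = field(default_factory=lambda: {"P1": 4, "P2": 4, "P3": 4, "O": 1})
    ne: float = 1.43e5
    split_p1p2: float = 3.0e5
    split_p12p3: float = 6.0e5
    split_root: float = 2.0e6
    pulse: Pulse | None = None
    mu: float = 3.5e-9
    gen_time: float = 3.0
    n_chrom: int = 22
    chrom_length: int = 500_000
    mean_tract_bp: float = 50_000.0

    def validate(self) -> None:
        if self.n_chrom < 1:
            raise IntrogrescanError("n_chrom must be >= 1")
        if not 0 < self.split_p1p2 < self.split_p12p3 < self.split_root:
            raise IntrogrescanError("split times must be ordered p1p2 < p12p3 < root")
        if any(p not in _POPS for p in self.samples):
            raise IntrogrescanError(f"unknown population in samples: {self.samples}")
        if self.pulse is not None:
            p = self.pulse
            if not 0.0 <= p.fraction <= 1.0:
                raise IntrogrescanError("pulse fraction must lie in [0, 1]")
            if p.donor not in _POPS or p.recipient not in _POPS:
                raise IntrogrescanError("pulse populations must be P1/P2/P3/O")
            lim = min(self._split_of(p.donor), self._split_of(p.recipient))
            if p.time >= lim:
                raise IntrogrescanError("pulse must postdate the donor/recipient split")

    def _split_of(self, pop: str) -> float:
        return {"P1": self.split_p1p2, "P2": self.split_p1p2,
                "P3": self.split_p12p3, "O": self.split_root}[pop]

    # ------------------------------------------------------------ conversions
    def to_msprime(self, aux_p3: int = 0, with_pulse: bool = True):
        """Build the msprime demography (optionally without the pulse)."""
        import msprime

        d = msprime.Demography()
        for p in _POPS + ("A12", "A123", "AR"):
            d.add_population(name=p, initial_size=self.ne)
        if with_pulse and self.pulse is not None and self.pulse.fraction > 0:
            d.add_mass_migration(time=self.pulse.time, source=self.pulse.recipient,
                                 dest=self.pulse.donor, proportion=self.pulse.fraction)
        d.add_population_split(time=self.split_p1p2, derived=["P1", "P2"], ancestral="A12")
        d.add_population_split(time=self.split_p12p3, derived=["A12", "P3"], ancestral="A123")
        d.add_population_split(time=self.split_root, derived=["A123", "O"], ancestral="AR")
        d.sort_events()
        return d

    def sample_names(self, aux_p3: int = 0) -> list[str]:
        names = []
        for p in _POPS:
            names += [f"{p}_{i}" for i in range(self.samples.get(p, 0))]
        names += [f"AUX_{i}" for i in range(aux_p3)]
        return names

    def sample_map(self) -> SampleMap:
        """Sample map treating each simulated diploid as its own species."""
        names = self.sample_names()
        species = {n: n for n in names}
        group = {}
        for n in names:
            group[n] = n.split("_")[0]
        roles = {r: {n for n in names if group[n] == r} for r in ("P1", "P2", "P3")}
        roles["outgroup"] = {n for n in names if group[n] == "O"}
        return SampleMap(sample=names, species=species, group=group, roles=roles)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Demography":
        d = dict(d)
        if d.get("pulse") is not None and not isinstance(d["pulse"], Pulse):
            d["pulse"] = Pulse(**d["pulse"])
        return cls(**d)


@dataclass
class Tract:
    """A donor-ancestry tract on one recipient haplotype."""

    chrom: str
    start: int
    end: int
    sample: str
    haplotype: int


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated :class:`SiteTable`."""

    demography: Demography
    seed: int
    tracts: list = field(default_factory=list)
    planted: dict = field(default_factory=dict)
    accessible_length: int | None = None
    mean_total_branch_length: float | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "demography": self.demography.to_dict(),
            "seed": self.seed,
            "tracts": [dataclasses.asdict(t) for t in self.tracts],
            "planted": self.planted,
            "accessible_length": self.accessible_length,
            "mean_total_branch_length": self.mean_total_branch_length,
        }
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------- internals

def _node_layout(d: Demography, aux_p3: int):
    """Sample-node bookkeeping: names and (node -> column) pairing."""
    import msprime

    sample_sets = [msprime.SampleSet(d.samples.get(p, 0), population=p, ploidy=2)
                   for p in _POPS if d.samples.get(p, 0) > 0]
    if aux_p3:
        sample_sets.append(msprime.SampleSet(aux_p3, population="P3", ploidy=2))
    n_dip = sum(d.samples.get(p, 0) for p in _POPS) + aux_p3
    return sample_sets, n_dip


def _pattern_stream(d: Demography, n_sites: int, seed: int, aux_p3: int = 0,
                    with_pulse: bool = True):
    """Yield derived-allele haplotype patterns from independent genealogies.

    Returns ``(hap, mean_ttot)``: an ``(n_sites, 2*n_dip)`` 0/1 matrix and
    the mean total branch length over *all* genealogies generated (accepted
    or not), which calibrates the implied accessible genome length.
    """
    import msprime

    d.validate()
    rng = np.random.default_rng(seed)
    sample_sets, n_dip = _node_layout(d, aux_p3)
    demog = d.to_msprime(with_pulse=with_pulse)
    hap = np.zeros((n_sites, 2 * n_dip), dtype=np.int8)
    got = 0
    t_sum = 0.0
    t_n = 0
    t_max = None
    while got < n_sites:
        batch = max(2000, int((n_sites - got) * 1.8))
        ms_seed = int(rng.integers(1, 2**31 - 1))
        reps = msprime.sim_ancestry(samples=sample_sets, demography=demog,
                                    num_replicates=batch, random_seed=ms_seed)
        for ts in reps:
            tab = ts.tables
            times = tab.nodes.time
            child = tab.edges.child
            bl = times[tab.edges.parent] - times[child]
            ttot = bl.sum()
            t_sum += ttot
            t_n += 1
            if t_max is None:
                # warm-up cap for branch-length-proportional acceptance
                t_max = 2.0 * ttot
            t_max = max(t_max, ttot)
            if ttot < rng.random() * t_max:
                continue
            cum = np.cumsum(bl)
            j = int(np.searchsorted(cum, rng.random() * ttot))
            tree = ts.first()
            der = np.fromiter(tree.samples(child[j]), dtype=np.int64)
            hap[got, der] = 1
            got += 1
            if got == n_sites:
                break
    return hap, t_sum / t_n


def _default_anno(n_sites: int, n_samples: int, dosage: np.ndarray,
                  rng: np.random.Generator):
    """Clean per-site annotations and balanced allele depths."""
    depth = rng.poisson(20, size=(n_sites, n_samples)).astype(np.int32)
    depth = np.maximum(depth, 4)
    ad_ref = np.zeros_like(depth)
    ad_alt = np.zeros_like(depth)
    hom_ref = dosage == 0
    hom_alt = dosage == 2
    het = dosage == 1
    ad_ref[hom_ref] = depth[hom_ref]
    ad_alt[hom_alt] = depth[hom_alt]
    ad_ref[het] = depth[het] // 2
    ad_alt[het] = depth[het] - depth[het] // 2
    miss = dosage == MISSING
    ad_ref[miss] = -1
    ad_alt[miss] = -1
    dp = np.where(dosage == MISSING, 0, depth).sum(axis=1)
    anno = pd.DataFrame({
        "MQ": np.full(n_sites, 60.0),
        "MQ0F": np.zeros(n_sites),
        "STRAND_P": np.full(n_sites, 0.5),
        "EXHET_P": np.full(n_sites, 0.5),
        "DP": dp.astype(float),
    })
    return anno, ad_ref, ad_alt


def _finish_table(d: Demography, hap: np.ndarray, names: list[str],
                  chrom: np.ndarray, pos: np.ndarray,
                  rng: np.random.Generator) -> SiteTable:
    """Pair haplotypes into dosages, randomise ref/alt coding, annotate."""
    n_sites = hap.shape[0]
    n_dip = len(names)
    dosage = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    # emulate an arbitrary reference: at ~40% of sites the reference carries
    # the derived allele, so the raw table needs outgroup polarization
    flip = rng.random(n_sites) < 0.4
    dosage[flip] = 2 - dosage[flip]
    ref = np.where(flip, "T", "A").astype(object)
    alt = np.where(flip, "A", "T").astype(object)
    anno, ad_ref, ad_alt = _default_anno(n_sites, n_dip, dosage, rng)
    t = SiteTable(chrom=chrom, pos=pos, ref=ref, alt=alt, dosage=dosage,
                  samples=names, anno=anno, ad_ref=ad_ref, ad_alt=ad_alt)
    t.validate()
    return t


# ------------------------------------------------------------ public modes

def simulate_site_patterns(d: Demography, n_sites: int, seed: int):
    """Unlinked mode: one independent genealogy per SNP.

    Sites are spread evenly over ``d.n_chrom`` chromosomes at the implied
    accessible-genome spacing, so per-site rates divided by
    ``truth.accessible_length`` are calibrated to ``d.mu``.

    Returns ``(SiteTable, SimTruth)``; byte-identical for a fixed seed.
    """
    d.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    hap, mean_ttot = _pattern_stream(d, n_sites, seed)
    acc_len = max(n_sites, int(round(n_sites / (d.mu * mean_ttot))))
    per_chrom = _split_counts(n_sites, d.n_chrom)
    chrom_len = acc_len // d.n_chrom
    chroms, pos = [], []
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        spacing = max(1, chrom_len // (k + 1))
        chroms += [f"chr{ci + 1}"] * k
        pos += [(i + 1) * spacing for i in range(k)]
    t = _finish_table(d, hap, d.sample_names(),
                      np.array(chroms, dtype=object), np.array(pos, dtype=np.int64), rng)
    truth = SimTruth(demography=d, seed=seed, accessible_length=acc_len,
                     mean_total_branch_length=mean_ttot)
    return t, truth


def simulate_tracts(d: Demography, seed: int, snps_per_chrom: int = 4000):
    """Linked mode: donor tracts planted on recipient haplotypes.

    The admixture fraction and tract scale come from ``d.pulse.fraction``
    and ``d.mean_tract_bp``.  Per recipient haplotype and chromosome the
    number of tracts is Poisson with mean ``f * L / mean_tract_bp`` and
    lengths are exponential, so the expected donor-ancestry span per
    haplotype is ``f * L`` (slightly less after clipping at chromosome ends
    and merging overlaps).  Inside a tract the haplotype's alleles are copied
    from a dedicated auxiliary donor haplotype, giving site genealogies that
    match the local ancestry exactly.
    """
    d.validate()
    f = d.pulse.fraction if d.pulse is not None else 0.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    rec_pop = d.pulse.recipient if d.pulse is not None else "P2"
    n_rec = d.samples.get(rec_pop, 0)
    aux = n_rec if f > 0 else 0
    n_sites = snps_per_chrom * d.n_chrom
    hap, _ = _pattern_stream(d, n_sites, seed, aux_p3=aux, with_pulse=False)

    L = d.chrom_length
    chroms = np.repeat([f"chr{i + 1}" for i in range(d.n_chrom)], snps_per_chrom).astype(object)
    pos = np.empty(n_sites, dtype=np.int64)
    for ci in range(d.n_chrom):
        p = np.sort(rng.choice(np.arange(1, L + 1), size=snps_per_chrom, replace=False))
        pos[ci * snps_per_chrom:(ci + 1) * snps_per_chrom] = p

    names_all = d.sample_names(aux_p3=aux)
    names_out = d.sample_names()
    # haplotype column index of each (population) sample name
    col_of = {n: 2 * i for i, n in enumerate(names_all)}
    rec_names = [f"{rec_pop}_{i}" for i in range(n_rec)]

    tracts: list[Tract] = []
    if f > 0:
        for ri, rn in enumerate(rec_names):
            for h in range(2):
                donor_col = col_of[f"AUX_{ri}"] + h
                rec_col = col_of[rn] + h
                for ci in range(d.n_chrom):
                    cname = f"chr{ci + 1}"
                    n_tr = rng.poisson(f * L / d.mean_tract_bp)
                    ivs = []
                    for _ in range(n_tr):
                        length = max(1, int(rng.exponential(d.mean_tract_bp)))
                        start = int(rng.integers(1, L + 1))
                        ivs.append((start, min(L, start + length - 1)))
                    for s, e in _merge(ivs):
                        tracts.append(Tract(cname, s, e, rn, h))
                        sl = slice(ci * snps_per_chrom, (ci + 1) * snps_per_chrom)
                        in_tract = (pos[sl] >= s) & (pos[sl] <= e)
                        idx = np.flatnonzero(in_tract) + ci * snps_per_chrom
                        hap[idx, rec_col] = hap[idx, donor_col]

    hap_out = hap[:, : 2 * len(names_out)]
    t = _finish_table(d, hap_out, names_out, chroms, pos, rng)
    truth = SimTruth(demography=d, seed=seed, tracts=tracts,
                     accessible_length=d.n_chrom * L)
    return t, truth


def _merge(ivs):
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _split_counts(n: int, k: int) -> list[int]:
    base = n // k
    extra = n % k
    return [base + (1 if i < extra else 0) for i in range(k)]


# ------------------------------------------------------- planted QC failures

#: per-rule annotation edits guaranteeing a single-rule violation
_PLANT_RULES = ("MQ", "MQ0F", "STRAND_P", "EXHET_P", "MISSING", "DEPTH",
                "ALLELE_BALANCE")


def plant_filter_failures(t: SiteTable, spec: dict, seed: int,
                          truth: SimTruth | None = None):
    """Make ``spec[rule]`` randomly chosen sites violate exactly that rule.

    The input is copied; chosen sites are distinct across rules.  Returns
    ``(SiteTable, SimTruth)`` where the truth's ``planted`` maps each rule to
    the doctored ``(chrom, pos)`` coordinates.
    """
    for rule in spec:
        if rule not in _PLANT_RULES:
            raise IntrogrescanError(f"unknown filter rule {rule!r}")
    total = sum(spec.values())
    if total > t.n_sites:
        raise IntrogrescanError("more planted failures than sites")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    out = t.take_sites(np.ones(t.n_sites, dtype=bool))
    if out.anno is None:
        out.anno, out.ad_ref, out.ad_alt = _default_anno(
            out.n_sites, out.n_samples, out.dosage, rng)
    chosen = rng.choice(out.n_sites, size=total, replace=False)
    planted: dict[str, list] = {}
    k = 0
    anno = out.anno
    for rule, count in spec.items():
        idx = chosen[k:k + count]
        k += count
        planted[rule] = [(str(out.chrom[i]), int(out.pos[i])) for i in idx]
        if rule == "MQ":
            anno.loc[idx, "MQ"] = 30.0
        elif rule == "MQ0F":
            anno.loc[idx, "MQ0F"] = 0.3
        elif rule == "STRAND_P":
            anno.loc[idx, "STRAND_P"] = 1e-5
        elif rule == "EXHET_P":
            anno.loc[idx, "EXHET_P"] = 0.01
        elif rule == "MISSING":
            n_miss = int(math.floor(0.2 * out.n_samples)) + 1
            for i in idx:
                cols = rng.choice(out.n_samples, size=n_miss, replace=False)
                out.dosage[i, cols] = MISSING
                if out.ad_ref is not None:
                    out.ad_ref[i, cols] = -1
                    out.ad_alt[i, cols] = -1
        elif rule == "DEPTH":
            dp = anno["DP"].to_numpy(dtype=float)
            hi = dp.mean() + 20.0 * max(dp.std(), 1.0) + 100.0
            anno.loc[idx, "DP"] = hi
        elif rule == "ALLELE_BALANCE":
            if out.ad_ref is None:
                _, out.ad_ref, out.ad_alt = _default_anno(
                    out.n_sites, out.n_samples, out.dosage, rng)
            for i in idx:
                j = int(rng.integers(out.n_samples))
                out.dosage[i, j] = 1
                out.ad_ref[i, j] = 30
                out.ad_alt[i, j] = 2
    if truth is None:
        truth = SimTruth(demography=Demography(), seed=seed)
    truth = dataclasses.replace(truth, planted=planted)
    return out, truth
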