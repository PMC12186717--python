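"""Core in-memory containers shared by every analysis stage.

The universal substrate is the :class:`SiteTable`: a matrix of per-sample
alternate (or, after polarization, derived) allele dosages at biallelic SNPs,
together with genome coordinates and the per-site quality annotations that the
filtering stage consumes.  Dosages are small integers in {0, 1, 2} with -1
standing for a missing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: sentinel dosage for a missing diploid genotype
MISSING = -1

#: annotation columns understood by the site filters
ANNO_COLUMNS = ("MQ", "MQ0F", "STRAND_P", "EXHET_P", "DP")


class IntrogrescanError(Exception):
    """Base error for this package."""


class SampleNotFoundError(IntrogrescanError):
    """A requested sample id is absent from the input."""


class MalformedRecordError(IntrogrescanError):
    """A variant record could not be interpreted."""


@dataclass
class SiteTable:
    """Biallelic-SNP genotype matrix with coordinates and annotations.

    Parameters
    ----------
    chrom, pos
        Genome coordinates, 1-based positions, strictly increasing within a
        chromosome.
    ref, alt
        Reference / alternate nucleotide per site.
    dosage
        ``(n_sites, n_samples)`` int8 array of alt-allele counts per diploid
        genotype; ``-1`` marks a missing genotype.  After :func:`polarize`
        the counts refer to the derived allele.
    samples
        Column labels for ``dosage``.
    anno
        Optional per-site annotation frame with any of the columns in
        :data:`ANNO_COLUMNS`.
    ad_ref, ad_alt
        Optional per-genotype allele depths (same shape as ``dosage``,
        ``-1`` = unavailable); consumed by the allele-balance filter.
    polarized
        Whether dosages count derived alleles relative to an outgroup.
    outgroup_het, outgroup_missing
        Per-site flags set by :func:`polarize`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    anno: pd.DataFrame | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    polarized: bool = False
    outgroup_het: np.ndarray | None = None
    outgroup_missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.samples = list(self.samples)
        if self.dosage.ndim != 2 or self.dosage.shape != (len(self.pos), len(self.samples)):
            raise IntrogrescanError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )

    # ------------------------------------------------------------------ sizes
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the container invariants; raise on violation."""
        d = self.dosage
        bad = (d < MISSING) | (d > 2)
        if bad.any():
            raise IntrogrescanError("dosage values outside {0,1,2,missing}")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise IntrogrescanError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------- selections
    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise SampleNotFoundError(name) from None

    def sample_indices(self, names) -> np.ndarray:
        return np.array([self.sample_index(n) for n in names], dtype=np.intp)

    def take_sites(self, mask_or_index) -> "SiteTable":
        """Row subset; accepts a boolean mask or an integer index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[idx],
            anno=None if self.anno is None else self.anno.iloc[idx].reset_index(drop=True),
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx],
            outgroup_het=None if self.outgroup_het is None else self.outgroup_het[idx],
            outgroup_missing=None if self.outgroup_missing is None else self.outgroup_missing[idx],
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.dosage == MISSING).mean(axis=1)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)


@dataclass
class SampleMap:
    """sample -> species -> group assignments plus analysis role sets.

    ``roles`` maps a role name (``P1``, ``P2``, ``P3``, ``outgroup``) to the
    set of *species* eligible for that slot in four-taxon tests.
    """

    sample: list[str]
    species: dict[str, str]
    group: dict[str, str]
    roles: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.sample if s not in self.species]
        if missing:
            raise IntrogrescanError(f"samples without species assignment: {missing}")
        for sp in set(self.species.values()):
            if sp not in self.group:
                raise IntrogrescanError(f"species without group assignment: {sp}")

    @classmethod
    def from_tsv(cls, path: str | Path, roles: dict | None = None) -> "SampleMap":
        """Read a 3-column (sample, species, group) tab-separated file."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "species", "group"], dtype=str)
        species = dict(zip(df["sample"], df["species"]))
        group = dict(zip(df["species"], df["group"]))
        return cls(sample=list(df["sample"]), species=species, group=group,
                   roles={k: set(v) for k, v in (roles or {}).items()})

    def samples_of_species(self, sp: str) -> list[str]:
        return [s for s in self.sample if self.species[s] == sp]

    def samples_of_group(self, g: str) -> list[str]:
        return [s for s in self.sample if self.group[self.species[s]] == g]

    def all_species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample:
            seen.setdefault(self.species[s], None)
        return list(seen)


@dataclass
class RegionMask:
    """1-based inclusive (chrom, start, end) intervals, e.g. inversions."""

    intervals: list[tuple]

    def normalized(self) -> "RegionMask":
        """Sort and merge overlapping/adjacent intervals per chromosome."""
        by_chrom: dict[str, list] = {}
        for c, s, e in self.intervals:
            if e < s:
                raise IntrogrescanError(f"interval end before start: {c}:{s}-{e}")
            by_chrom.setdefault(str(c), []).append((int(s), int(e)))
        merged = []
        for c in sorted(by_chrom):
            ivs = sorted(by_chrom[c])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((c, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((c, cur_s, cur_e))
        return RegionMask(merged)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask of coordinates falling inside any interval."""
        inside = np.zeros(len(pos), dtype=bool)
        for c, s, e in self.intervals:
            inside |= (chrom.astype(str) == str(c)) & (pos >= s) & (pos <= e)
        return inside

    @classmethod
    def from_bed(cls, path: str | Path, one_based: bool = False) -> "RegionMask":
        """Read a BED-like TSV.

        With ``one_based=False`` (BED convention) starts are 0-based
        half-open and are shifted to 1-based inclusive; with
        ``one_based=True`` coordinates are taken verbatim (the convention in
        which inversion intervals are usually printed).
        """
        ivs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e = line.split("\t")[:3]
            s, e = int(s), int(e)
            if not one_based:
                s += 1
            ivs.append((c, s, e))
        return cls(ivs).normalized()
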