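"""Shared fixtures: hand-built site tables and small simulated data sets."""

import numpy as np
import pandas as pd
import pytest

from introgrescan import Demography, SiteTable, polarize, simulate_site_patterns
from introgrescan.core import MISSING


def make_table(pos, dosage, chrom=None, samples=None, anno=None,
               ad_ref=None, ad_alt=None):
    """Small hand-rolled SiteTable; positions 1-based, dosage row-per-site."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(m)]
    if chrom is None:
        chrom = ["chr1"] * n
    if anno is not None:
        anno = pd.DataFrame(anno)
    return SiteTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        dosage=dosage,
        samples=samples,
        anno=anno,
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
    )


def clean_anno(n, dp=140.0):
    """All-passing annotation block for n sites."""
    return {
        "MQ": [60.0] * n,
        "MQ0F": [0.0] * n,
        "STRAND_P": [0.5] * n,
        "EXHET_P": [0.5] * n,
        "DP": [dp] * n,
    }


@pytest.fixture(scope="session")
def toy_demog():
    return Demography(samples={"P1": 2, "P2": 2, "P3": 2, "O": 1}, n_chrom=4)


@pytest.fixture(scope="session")
def null_sim(toy_demog):
    """A no-gene-flow unlinked simulation shared across read-only tests."""
    t, truth = simulate_site_patterns(toy_demog, 6000, seed=42)
    return polarize(t, "O_0"), truth


@pytest.fixture(scope="session")
def null_roles():
    return {
        "P1": ["P1_0", "P1_1"],
        "P2": ["P2_0", "P2_1"],
        "P3": ["P3_0", "P3_1"],
        "outgroup": ["O_0"],
    }


MISSING = MISSING
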