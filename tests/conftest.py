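"""Shared fixtures: compact table construction and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from mitokit.simulate import SimConfig, simulate_cohort
from mitokit.table import MISSING, MitoVariantTable


def make_table(sites, genotypes, animals=None):
    """Build a MitoVariantTable from compact per-site specs.

    sites: list of (pos, ref, [alts], qual, mq)
    genotypes: per animal, list over sites of either None (missing) or
        ((a, b), [allele depths...])
    """
    n_animals = len(genotypes)
    if animals is None:
        animals = [f"A{i + 1}" for i in range(n_animals)]
    n_sites = len(sites)
    a_max = max(1 + len(s[2]) for s in sites)
    gt = np.full((n_animals, n_sites, 2), MISSING, dtype=np.int16)
    ad = np.zeros((n_animals, n_sites, a_max), dtype=np.int32)
    dp = np.zeros((n_animals, n_sites), dtype=np.int32)
    for i, row in enumerate(genotypes):
        for j, cell in enumerate(row):
            if cell is None:
                continue
            (a, b), depths = cell
            gt[i, j] = (a, b)
            ad[i, j, : len(depths)] = depths
            dp[i, j] = sum(depths)
    return MitoVariantTable(
        positions=np.array([s[0] for s in sites], dtype=np.int64),
        ref=[s[1] for s in sites],
        alt=[list(s[2]) for s in sites],
        qual=np.array([s[3] for s in sites], dtype=float),
        mq=np.array([s[4] for s in sites], dtype=float),
        animals=animals,
        gt=gt, ad=ad, dp=dp)


def make_metadata(animals, sex="F", tissue="blood", breed="BreedX", country="Nowhere"):
    def pick(val, i):
        return val[i] if isinstance(val, (list, tuple)) else val
    return pd.DataFrame({
        "animal_id": animals,
        "breed": [pick(breed, i) for i in range(len(animals))],
        "country": [pick(country, i) for i in range(len(animals))],
        "sex": [pick(sex, i) for i in range(len(animals))],
        "tissue": [pick(tissue, i) for i in range(len(animals))],
    })


NOISELESS = SimConfig(n_animals=40, n_haplogroups=3, defining_variants_per_group=8,
                      private_mutation_rate=2.0, heteroplasmy_rate_somatic=0.0,
                      heteroplasmy_rate_semen=0.0, missing_rate=0.0, indel_rate=0.0,
                      seed=11)

NOISY = SimConfig(n_animals=40, n_haplogroups=3, defining_variants_per_group=8,
                  private_mutation_rate=2.0, heteroplasmy_rate_somatic=0.01,
                  heteroplasmy_rate_semen=0.08, missing_rate=0.01,
                  indel_rate=0.001, low_qual_fraction=0.05, low_mq_fraction=0.05,
                  seed=13)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Heteroplasmy-, missing- and INDEL-free cohort with exact truth."""
    return simulate_cohort(NOISELESS)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort exercising heteroplasmy, missingness, INDELs and low QUAL/MQ."""
    return simulate_cohort(NOISY)
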