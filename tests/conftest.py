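import dataclasses

import numpy as np
import pandas as pd
import pytest

from weanotype import cohort
from weanotype.tables import CountTable, SampleMetadata, TaxonomyMap


@pytest.fixture(scope="session")
def default_config():
    return cohort.calibrate_default_config()


@pytest.fixture(scope="session")
def small_config(default_config):
    """Reduced cohort (4 farms x 10 pigs) for fast unit tests."""
    return dataclasses.replace(
        default_config, n_farms=4, pigs_per_farm=10,
        missing_farm_d26=None, missing_farm_d35=None,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cohort.generate(small_config, seed=11)


@pytest.fixture()
def toy_counts():
    return CountTable(pd.DataFrame(
        [[5, 0, 2], [1, 3, 0]],
        index=["s1", "s2"], columns=["o1", "o2", "o3"],
    ))


@pytest.fixture()
def toy_taxonomy():
    return TaxonomyMap(pd.DataFrame(
        {
            "phylum": ["Firmicutes", "Firmicutes", "unknown"],
            "family": ["Lachnospiraceae", "Lachnospiraceae", "unknown"],
            "genus": ["Blautia", "Roseburia", "unknown"],
        },
        index=["o1", "o2", "o3"],
    ))


def make_metadata(n_pigs=6, n_farms=2, seed=0):
    """Two samples per pig with simple weights; helper for growth tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pigs):
        farm = i % n_farms + 1
        pig = f"P{i:02d}"
        w26 = 7.0 + rng.uniform(0, 3)
        w48 = w26 + rng.uniform(3, 8)
        for age in ("d26", "d35"):
            rows.append({
                "sample_id": f"{pig}.{age}", "pig_id": pig, "farm_id": farm,
                "age_point": age, "weight_d26": w26,
                "weight_d35": w26 + 1.0, "weight_d48": w48,
                "interval_days": 22,
            })
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
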