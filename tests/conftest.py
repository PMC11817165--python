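import numpy as np
import pandas as pd
import pytest

from durumcolor import datasets
from durumcolor.synthetic_data import SimulationConfig, simulate_trial
from durumcolor.trait_model import TraitTable


def make_table(values: np.ndarray, trait: str = "YI_S") -> TraitTable:
    """Build a single-trait TraitTable from a (p, q, r) value cube."""
    p, q, r = values.shape
    rows = [
        {
            "genotype": f"G{g + 1:02d}",
            "environment": f"ENV{e + 1}",
            "replicate": k + 1,
            "trait": trait,
            "value": float(values[g, e, k]),
        }
        for g in range(p)
        for e in range(q)
        for k in range(r)
    ]
    return TraitTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_trial() -> TraitTable:
    """One full-size simulated trial under the default study conditions."""
    return simulate_trial(SimulationConfig(seed=20260926))


@pytest.fixture(scope="session")
def genotype_means() -> pd.DataFrame:
    return datasets.genotype_means()


@pytest.fixture(scope="session")
def env_means() -> pd.DataFrame:
    return datasets.environment_means()


@pytest.fixture(scope="session")
def trait_corr() -> pd.DataFrame:
    return datasets.trait_correlations()


@pytest.fixture(scope="session")
def env_spi() -> pd.DataFrame:
    return datasets.environment_spi()
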