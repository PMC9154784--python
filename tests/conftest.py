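import numpy as np
import pandas as pd
import pytest

from fmtx import de as de_mod
from fmtx import synthio
from fmtx.io import CountTable


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort shared across tests (seed 1)."""
    return synthio.simulate_dataset(synthio.SimulationConfig())


@pytest.fixture(scope="session")
def default_contrasts(default_dataset):
    """DE results for all four contrasts on the default cohort."""
    data = default_dataset
    return de_mod.run_contrasts(data.gene_counts, data.gene_meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_count_table(matrix, features=None, samples=None) -> CountTable:
    matrix = np.asarray(matrix)
    features = features or [f"f{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return CountTable(pd.DataFrame(matrix, index=features, columns=samples))
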