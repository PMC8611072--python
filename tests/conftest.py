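import numpy as np
import pandas as pd
import pytest

from regmodkit import SimulationConfig, TimeCourseMatrix, generate_dataset
from regmodkit import devreg


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the default generator conditions, shared across tests."""
    return generate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    """Quantile-normalized matrices of the default dataset."""
    ds = default_dataset
    dhs = TimeCourseMatrix(
        devreg.quantile_normalize(ds.dhs_matrix.values), ds.dhs_matrix.samples
    )
    gene = TimeCourseMatrix(
        devreg.quantile_normalize(ds.gene_matrix.values), ds.gene_matrix.samples
    )
    return dhs, gene


@pytest.fixture(scope="session")
def small_dataset():
    """A small dataset for fast structural tests."""
    return generate_dataset(SimulationConfig(n_dhs=300, n_genes=80, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_tcm():
    """Factory for a TimeCourseMatrix from a values array and day vector."""

    def _make(values, days, feature_ids=None):
        values = np.asarray(values, dtype=float)
        n = values.shape[1]
        days = np.asarray(days)
        cols = [f"s{i}" for i in range(n)]
        samples = pd.DataFrame(
            {"donor": [f"d{i % 3 + 1}" for i in range(n)], "day": days}, index=cols
        )
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(values.shape[0])]
        return TimeCourseMatrix(
            pd.DataFrame(values, index=feature_ids, columns=cols), samples
        )

    return _make
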