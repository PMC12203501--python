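import numpy as np
import pytest

from subloc3d import (
    DatasetTable,
    SimConfig,
    simulate_dataset,
    simulate_kg,
    split_by_protein,
)

#: small, cheap-to-render study conditions shared by unit tests
TINY = dict(shape=(8, 16, 16), n_proteins=8, cells_per_protein=4, seed=7)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    """(table, truth) for a 32-cell synthetic screen; session-cached."""
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset, tiny_config):
    table, _ = tiny_dataset
    return simulate_kg(table, tiny_config)


@pytest.fixture()
def tiny_table(tiny_dataset) -> DatasetTable:
    """Fresh split assignment per test (splits mutate sample state)."""
    table, _ = tiny_dataset
    split_by_protein(table, seed=0)
    return table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
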