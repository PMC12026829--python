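import numpy as np
import pytest

from gsbench import (
    SimulationConfig,
    compute_grm,
    make_partitions,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """200 lines x 800 markers, h^2 = 0.5, clean."""
    return simulate_dataset(SimulationConfig(n_lines=200, n_markers=800, seed=42))


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return compute_grm(small_dataset.markers)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return make_partitions(small_dataset.line_ids, n_reps=1, master_seed=7).splits[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
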