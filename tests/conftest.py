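import numpy as np
import pytest

from netmod import WeightedMatrix
from netmod.synth import (
    generate_modular_network,
    generate_traits,
    occurrence_like_spec,
)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    A = rng.integers(0, 4, size=(10, 6))
    A[A.sum(axis=1) == 0, 0] = 1
    A[0, A.sum(axis=0) == 0] = 1
    return WeightedMatrix(A, [f"r{i}" for i in range(10)], [f"c{j}" for j in range(6)])


@pytest.fixture(scope="session")
def planted_dataset():
    """A small planted-structure dataset shared across tests."""
    spec = occurrence_like_spec(
        seed=7, n_resources=40, n_consumers=12, n_modules=4, total_events=600,
        mixing=0.05,
    )
    m, partition, meta = generate_modular_network(spec)
    traits = generate_traits(partition, m.col_labels, convergence=0.8, seed=11)
    return m, partition, meta, traits
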