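import numpy as np
import pytest

from morphodrift import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cranium_dataset():
    """Study-shaped synthetic cranium sample: 24 landmarks, 4 localities."""
    return simulate_dataset(SimulationConfig(k=24, g=4, seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset: 8 landmarks, 3 localities of 10."""
    return simulate_dataset(SimulationConfig(k=8, g=3, n_per_group=10, seed=1))
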