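import numpy as np
import pytest

from rbnres import ReservoirConfig, generate_reservoir


@pytest.fixture(scope="session")
def small_reservoir():
    """A small near-critical inhibitory reservoir shared across tests."""
    return generate_reservoir(ReservoirConfig(200, 16, -0.66, seed=42))


@pytest.fixture(scope="session")
def large_reservoir():
    """Full-width reservoir (160,000 synapses) for law-of-large-numbers checks."""
    return generate_reservoir(ReservoirConfig(10_000, 16, 4.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
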