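import numpy as np
import pytest

from qdyefinder.quality_control import QCConfig, run_qc
from qdyefinder.synthesis import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """8-neuron, 7-channel noiseless phantom shared across tests."""
    cfg = PhantomConfig(n_neurons=8, n_channels=7, shape=(16, 64, 64), seed=3)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom_qc(small_phantom):
    """QC output (vectors, fragments, report) for the shared phantom."""
    vectors, frags, report = run_qc(
        small_phantom.fragments,
        small_phantom.image,
        QCConfig(min_length_um=5.0, min_magnitude=0.1),
    )
    return vectors, frags, report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
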