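import numpy as np
import pytest

from fogcast.synth import GaitSimParams, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, outlier-free generator settings for signal-shape checks."""
    return GaitSimParams(noise_sd=0.0, burst_outlier_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def basic_recording():
    """One 60-s recording with a single mid-recording freeze."""
    params = GaitSimParams(seed=7)
    return simulate_recording(params, 60.0, [(30.0, 5.0)])
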