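import numpy as np
import pytest

from posturelab import SimulationConfig, default_stimulus, generate_study, make_stimulus


@pytest.fixture(scope="session")
def default_stim():
    return default_stimulus()


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-rate, short-duration simulator config for cheap tests."""
    return SimulationConfig(sample_rate=200.0, spont_duration=10.0, calib_duration=40.0)


@pytest.fixture(scope="session")
def fast_stimulus():
    """Short tilt stimulus matched to fast_config: 4-s cycles, 5 cycles, 200 Hz."""
    return make_stimulus(state_duration=0.05, n_cycles=5, sample_rate=200.0)


@pytest.fixture(scope="session")
def fast_study(fast_config, fast_stimulus):
    return generate_study(fast_config, n_subjects=3, seed=11, stimulus=fast_stimulus)


@pytest.fixture(scope="session")
def full_study():
    """Full-protocol 10-subject study at 1000 Hz (used by acceptance tests)."""
    return generate_study(SimulationConfig(), n_subjects=10, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
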