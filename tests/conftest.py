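import numpy as np
import pytest

from boilstart import AcquisitionConfig, SimulationConfig


@pytest.fixture
def small_config():
    """Tiny acquisition profile: 8 kHz, 0.1 s, 4 segments of 200 samples."""
    return AcquisitionConfig(sampling_rate_hz=8000.0, collection_duration_s=0.1,
                             acquisition_period_s=30.0, n_segments=4)


@pytest.fixture
def sim_config():
    """Standard scaled simulation scenario with a fixed seed."""
    return SimulationConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
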