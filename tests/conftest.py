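import numpy as np
import pytest

from kneeadl.activities import default_profiles
from kneeadl.simulate import SimulationConfig
from kneeadl.stream_io import ImuStream


@pytest.fixture
def profiles():
    return default_profiles()


@pytest.fixture
def quiet_config():
    """Simulator config with all stochastic corruption disabled."""
    return SimulationConfig().without_noise()


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


def make_stream(t_ms, device="femoral", value=1.0):
    """Constant-valued stream at the given timestamps."""
    n = len(t_ms)
    return ImuStream(
        device_id=device,
        t_ms=np.asarray(t_ms, dtype=np.int64),
        accel=np.full((n, 3), value),
        gyro=np.full((n, 3), value),
    )
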