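import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_session():
    """60 s, 60 rpm, noise-free two-sided session with ground truth."""
    from pedalkin import NOISELESS, make_session

    return make_session(duration=60.0, cadence_profile=60.0, noise=NOISELESS, seed=0)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise session (σ_accel=0.5 m/s², σ_gyro=0.02 rad/s)."""
    from pedalkin import SensorNoiseModel, make_session

    return make_session(duration=60.0, noise=SensorNoiseModel(seed=7), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
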