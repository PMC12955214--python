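import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_eye():
    """A 60-ommatidium synthetic eye with exact (noise-free) markers."""
    from optomotor import SyntheticEyeSpec, generate_synthetic_eye

    return generate_synthetic_eye(
        SyntheticEyeSpec(n_ommatidia=60, marker_noise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def noiseless_eye_model(noiseless_eye):
    from optomotor import build_eye_model

    return build_eye_model(noiseless_eye.markers)


@pytest.fixture(scope="session")
def noisy_walk():
    """Circling bout at 120 deg/s with 0.2 mm tracking noise."""
    from optomotor import SyntheticWalkSpec, generate_walk_trajectory

    return generate_walk_trajectory(
        SyntheticWalkSpec(turning_velocity=120.0, position_noise_sd=0.2, seed=7)
    )
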