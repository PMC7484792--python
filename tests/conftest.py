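import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from footpower.synthetic_data import SyntheticTrialSpec, generate_trial

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trial():
    """One deterministic noiseless synthetic trial with its ground truth."""
    spec = SyntheticTrialSpec(seed=1, marker_noise_sd=0.0, force_noise_sd=0.0)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def noisy_trial():
    """Default (realistic measurement noise) synthetic trial."""
    spec = SyntheticTrialSpec(seed=2)
    return generate_trial(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
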