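import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quatfall import DetectorConfig, MotionSpec, generate, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def fall_forward_42():
    """Canonical forward-fall trace: still, dip, impact, ring-down, lying."""
    return generate(MotionSpec("fall_forward", seed=42))


@pytest.fixture(scope="session")
def jumping_42():
    return generate(MotionSpec("jumping", seed=42))


@pytest.fixture(scope="session")
def resting_42():
    return generate(MotionSpec("resting", seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Two traces per motion class; enough to exercise the benchmark."""
    return generate_cohort(2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
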