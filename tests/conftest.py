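import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def reference_table():
    from alcofit.reference import load_reference_strata

    return load_reference_strata()


@pytest.fixture(scope="session")
def gamma_volumes():
    """A large seeded gamma sample shared by fitting tests (k=0.44, theta=48)."""
    return np.random.default_rng(42).gamma(0.44, 48.0, 50_000)
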