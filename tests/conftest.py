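import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avcea import ParameterSet, default_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def cohort():
    return default_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
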