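import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# LSODA grumbles on the (expected) diverging M2b/M2d trajectories.
warnings.filterwarnings(
    "ignore", message=".*lsoda.*", category=UserWarning)


@pytest.fixture(scope="session")
def all_ones():
    from notchcis.synth import fixture_params
    return fixture_params("all_ones")


@pytest.fixture(scope="session")
def m2c_nonmono():
    from notchcis.synth import fixture_params
    return fixture_params("m2c_nonmonotonic")


@pytest.fixture(scope="session")
def no_binding():
    from notchcis.synth import fixture_params
    return fixture_params("no_binding")
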