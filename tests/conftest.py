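import pytest
from hypothesis import HealthCheck, settings

import arterywall as aw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return aw.DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def default_ss():
    """Full-model steady state at default inputs via integrate-then-polish."""
    ss = aw.find_steady_state(aw.DEFAULT_INPUTS, aw.make_variant("GROWTH"))
    assert ss.stable
    return ss


@pytest.fixture(scope="session")
def analytic_fp():
    """Independent semi-analytic full-model fixed point at default inputs."""
    return aw.solve_growth_fixed_point(aw.DEFAULT_INPUTS)


@pytest.fixture(scope="session")
def sensitivity():
    """±5% central-difference sensitivity matrix (integrate-then-polish)."""
    return aw.sensitivity_matrix()
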