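import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lltsim import (  # noqa: E402
    EfficacyPoolRule,
    SimulationConfig,
    calibrate_ldl_model,
    default_constraints,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_rule():
    return EfficacyPoolRule.default()


@pytest.fixture(scope="session")
def constraints():
    return default_constraints()


@pytest.fixture(scope="session")
def ldl_model(constraints):
    return calibrate_ldl_model(constraints)


@pytest.fixture(scope="session")
def sim_cohort(constraints, ldl_model):
    """The default calibrated synthetic simulation cohort (N=144)."""
    return generate_cohort(constraints, ldl_model, seed=1)


@pytest.fixture()
def small_config():
    return SimulationConfig(n_reps=200, master_seed=11)
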