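import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cryodepth import (
    BoundaryCondition,
    SolverConfig,
    average_cooling_boundary,
    bf_from_bmi,
    diffusivity_from_bf,
    solve,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

STEP_TS = 10.0
STEP_T0 = 37.0
STEP_ALPHA = 0.149e-6


@pytest.fixture(scope="session")
def step_field():
    """Default-resolution solve for a surface step 37 -> 10 degC."""
    b = BoundaryCondition(times=[0.0, 1800.0], temps=[STEP_TS, STEP_TS], deep_temp_T0=STEP_T0)
    return solve(b, STEP_ALPHA, SolverConfig())


@pytest.fixture(scope="session")
def average_run():
    """Cohort-average boundary solve: exponential 32.1 -> 18.2, cohort-median
    anthropometrics (BMI 22, age 80, female), core 37 degC."""
    alpha = diffusivity_from_bf(bf_from_bmi(22.0, 80.0, "female"))
    field = solve(average_cooling_boundary(), alpha, SolverConfig())
    return field, alpha
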