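"""Crank-Nicolson solver against analytic and structural oracles."""

import dataclasses
import math

import numpy as np
import pytest

from cryodepth import (
    BoundaryCondition,
    SolverConfig,
    analytic_semi_infinite,
    interpolate_boundary,
    solve,
)
from .conftest import STEP_ALPHA, STEP_T0, STEP_TS


# --- boundary interpolation -------------------------------------------------

@pytest.mark.parametrize(
    "times, temps, query_idx, expected",
    [
        ([0, 1800], [30, 30], 900, 30.0),            # constant trace
        ([0, 10], [32, 22], 5, 27.0),                # linear midpoint
        ([0, 300, 1800], [32.1, 20, 18.2], 150, 26.05),  # hand interpolation
    ],
)
def test_interpolate_boundary_values(times, temps, query_idx, expected):
    grid = interpolate_boundary(np.array(times), np.array(temps), dt=1.0,
                                duration=times[-1])
    assert grid[query_idx] == pytest.approx(expected, abs=1e-12)
    assert grid[0] == temps[0] and grid[-1] == temps[-1]  # endpoints exact


def test_interpolate_boundary_too_short():
    with pytest.raises(ValueError, match="needs"):
        interpolate_boundary(np.array([0.0, 600.0]), np.array([30.0, 20.0]),
                             dt=1.0, duration=1800.0)


# --- analytic oracle --------------------------------------------------------

def test_analytic_semi_infinite_values():
    assert analytic_semi_infinite(10, 37, STEP_ALPHA, 0.0, 100.0) == 10.0
    # x = 2 sqrt(alpha t): erf(1) = 0.8427
    t = 1800.0
    x = 2 * math.sqrt(STEP_ALPHA * t)
    assert analytic_semi_infinite(10, 37, STEP_ALPHA, x, t) == pytest.approx(
        10 + 27 * 0.84270079, abs=1e-6
    )
    # far field returns the initial temperature (erf argument 6)
    x_far = 12 * math.sqrt(STEP_ALPHA * t)
    assert analytic_semi_infinite(10, 37, STEP_ALPHA, x_far, t) == pytest.approx(37.0, abs=1e-6)
    with pytest.raises(ValueError):
        analytic_semi_infinite(10, 37, STEP_ALPHA, 0.01, 0.0)


# --- solver correctness -----------------------------------------------------

def test_equilibrium_is_fixed_point():
    b = BoundaryCondition(times=[0.0, 1800.0], temps=[37.0, 37.0], deep_temp_T0=37.0)
    f = solve(b, STEP_ALPHA)
    assert np.abs(f.values - 37.0).max() < 1e-10


def test_step_boundary_matches_erf_oracle(step_field):
    """|CN - closed form| < 0.05 degC for x <= 3 cm, 60 s <= t <= 1800 s."""
    for x in (0.002, 0.005, 0.01, 0.02, 0.03):
        trace = step_field.at_depth(x)
        for t in (60, 120, 300, 600, 900, 1200, 1800):
            exact = analytic_semi_infinite(STEP_TS, STEP_T0, STEP_ALPHA, x, float(t))
            assert abs(trace[t] - exact) < 0.05


def test_second_order_convergence():
    """Halving dt and dx shrinks the oracle error ~4x (second order)."""
    b = BoundaryCondition(times=[0.0, 1800.0], temps=[STEP_TS, STEP_TS], deep_temp_T0=STEP_T0)
    errors = []
    for k in (1, 2):
        cfg = SolverConfig(dx=1e-4 / k, dt=1.0 / k)
        f = solve(b, STEP_ALPHA, cfg)
        exact = analytic_semi_infinite(STEP_TS, STEP_T0, STEP_ALPHA, 0.01, 1800.0)
        errors.append(abs(f.at_depth(0.01)[-1] - exact))
    ratio = errors[0] / errors[1]
    assert 3.0 < ratio < 5.0


def test_maximum_principle_smooth_boundary(average_run):
    """No node overshoots the boundary/initial extremes (smooth cooling)."""
    field, _ = average_run
    assert field.values.max() <= 37.0 + 0.1
    assert field.values.min() >= 18.2 - 0.1


def test_linearity_temperature_shift():
    """Shifting boundary and T0 by a constant shifts the field identically."""
    cfg = SolverConfig(dx=1e-3, dt=10.0)
    times = np.array([0.0, 300.0, 1800.0])
    temps = np.array([32.0, 22.0, 18.0])
    f1 = solve(BoundaryCondition(times=times, temps=temps, deep_temp_T0=37.0), STEP_ALPHA, cfg)
    f2 = solve(BoundaryCondition(times=times, temps=temps - 10.0, deep_temp_T0=27.0),
               STEP_ALPHA, cfg)
    assert np.abs((f1.values - 10.0) - f2.values).max() < 1e-9


def test_steady_state_linear_profile():
    """Held surface + long run relaxes to the straight conduction profile."""
    alpha = 0.13e-6
    L = 0.02
    duration = 10 * L**2 / alpha
    duration = round(duration / 20.0) * 20.0
    cfg = SolverConfig(L=L, dx=5e-4, dt=20.0, duration=duration)
    b = BoundaryCondition(times=[0.0, duration], temps=[10.0, 10.0], deep_temp_T0=37.0)
    f = solve(b, alpha, cfg)
    line = 10.0 + (37.0 - 10.0) * f.depths / L
    assert np.abs(f.values[:, -1] - line).max() < 0.1


def test_rannacher_startup_damps_step_ringing():
    """A discontinuous start makes plain CN undershoot the boundary value;
    the two implicit half-steps remove the ringing without losing accuracy."""
    b = BoundaryCondition(times=[0.0, 1800.0], temps=[STEP_TS, STEP_TS], deep_temp_T0=STEP_T0)
    plain = solve(b, STEP_ALPHA, SolverConfig())
    damped = solve(b, STEP_ALPHA, SolverConfig(rannacher_startup=True))
    assert plain.values.min() < STEP_TS - 0.1          # ringing present
    assert damped.values.min() >= STEP_TS - 1e-9        # ringing removed
    exact = analytic_semi_infinite(STEP_TS, STEP_T0, STEP_ALPHA, 0.01, 1800.0)
    assert abs(damped.at_depth(0.01)[-1] - exact) < 0.05


# --- validation -------------------------------------------------------------

def test_boundary_validation():
    with pytest.raises(ValueError):  # NaN temperature
        BoundaryCondition(times=[0.0, 10.0], temps=[30.0, float("nan")], deep_temp_T0=37.0)
    with pytest.raises(ValueError):  # not starting at 0
        BoundaryCondition(times=[5.0, 10.0], temps=[30.0, 29.0], deep_temp_T0=37.0)
    with pytest.raises(ValueError):  # out of physical range
        BoundaryCondition(times=[0.0, 10.0], temps=[30.0, 50.0], deep_temp_T0=37.0)


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(L=0.10, dx=3e-4)  # L/dx not integer
    with pytest.raises(ValueError):
        SolverConfig(dt=-1.0)


def test_field_boundary_values_preserved(average_run):
    field, _ = average_run
    assert field.values[0, 0] == pytest.approx(32.1, abs=1e-9)
    assert field.values[0, -1] == pytest.approx(18.2, abs=1e-9)  # boundary hits 18.2 at 30 min
    assert np.all(field.values[-1, :] == 37.0)   # deep Dirichlet node
    assert np.all(field.values[1:, 0] == 37.0)   # initial condition at T0
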