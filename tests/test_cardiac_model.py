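"""Unit and property tests for the closed-loop haemodynamic model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvsloppy as cv
from cvsloppy.cardiac_model import (InvalidTimingError, SimulationFailure,
                                    Trajectory, output_grid, table1)

TAU = cv.TAU


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t_tilde, expected", [
    (0.0, 0.0),                 # cos(0) = 1 forces e = 0
    (0.2, 1.0),                 # end of systolic rise
    (0.1, 0.5),                 # cos(pi/2) = 0 halfway up
    (0.35, 0.0),                # past end-pulse: relaxed
])
def test_activation_values(t_tilde, expected):
    assert cv.activation(t_tilde, 0.2, 0.3, TAU) == pytest.approx(expected)


def test_activation_rejects_inverted_timing():
    with pytest.raises(InvalidTimingError):
        cv.activation(0.1, 0.3, 0.2, TAU)


@given(st.floats(0.0, TAU, exclude_max=True))
@settings(max_examples=100, derandomize=True)
def test_activation_bounded_and_continuous(t):
    e = cv.activation(t, 0.218, 0.366, TAU)
    assert 0.0 <= e <= 1.0
    # continuity: a small step never jumps the activation
    h = 1e-9
    if t + h < TAU:
        assert abs(cv.activation(t + h, 0.218, 0.366, TAU) - e) < 1e-5


def test_elastance_baseline_lv():
    lv = table1().lv
    assert cv.elastance(0.0, lv) == pytest.approx(0.07)        # E_min at t=0
    assert cv.elastance(lv.tau_es, lv) == pytest.approx(2.8)   # E_max at t_es


@pytest.mark.parametrize("label", ["lv", "rv", "la", "ra"])
def test_elastance_periodic_and_bounded(label):
    ch = table1().chamber(label)
    t = np.linspace(0.0, TAU, 113, endpoint=False)
    vals = np.array([cv.elastance(tk, ch) for tk in t])
    shifted = np.array([cv.elastance(tk + TAU, ch) for tk in t])
    np.testing.assert_allclose(vals, shifted, rtol=0, atol=1e-12)
    assert np.all(vals >= ch.E_min - 1e-12)
    assert np.all(vals <= ch.E_max + 1e-12)


def test_chamber_pressure_examples():
    lv = table1().lv
    # zero stressed volume -> zero pressure at any phase
    for t in (0.0, 0.1, 0.5):
        assert cv.chamber_pressure(lv.V0, t, lv) == pytest.approx(0.0)
    assert cv.chamber_pressure(120.0, lv.tau_es, lv) == pytest.approx(280.0)
    assert cv.chamber_pressure(169.6, 0.0, lv) == pytest.approx(10.472)


@given(st.floats(-50, 300), st.floats(-50, 300),
       st.floats(1e-4, 10.0))
@settings(max_examples=100, derandomize=True)
def test_valve_flow_diode(p_up, p_down, r):
    q = cv.valve_flow(p_up, p_down, r)
    assert q >= 0.0
    if p_up > p_down:
        assert q == pytest.approx((p_up - p_down) / r)
    else:
        assert q == 0.0


def test_valve_flow_example():
    assert cv.valve_flow(10.0, 5.0, 0.01) == pytest.approx(500.0)


# ---------------------------------------------------------------------------
# Right-hand side against an independently assembled flow balance
# ---------------------------------------------------------------------------

def _flow_balance_oracle(t, V, p):
    """Hand-assembled pairwise flows for the loop topology, built only from
    the public scalar relations."""
    P = {c: cv.chamber_pressure(V[i], t, p.chamber(c))
         for i, c in enumerate(("lv", "rv", "la", "ra"))}
    circ = p.circulation
    P["sa"] = V[4] / circ.C_sa
    P["sv"] = V[5] / circ.C_sv
    P["pa"] = V[6] / circ.C_pa
    P["pv"] = V[7] / circ.C_pv
    q_mitral = cv.valve_flow(P["la"], P["lv"], p.la.R_valve)
    q_aortic = cv.valve_flow(P["lv"], P["sa"], p.lv.R_valve)
    q_sys = (P["sa"] - P["sv"]) / (circ.R_sa + circ.R_svb)
    q_sv = (P["sv"] - P["ra"]) / circ.R_sv
    q_tricuspid = cv.valve_flow(P["ra"], P["rv"], p.ra.R_valve)
    q_pulm_valve = cv.valve_flow(P["rv"], P["pa"], p.rv.R_valve)
    q_pul = (P["pa"] - P["pv"]) / (circ.R_pa + circ.R_pvb)
    q_pv = (P["pv"] - P["la"]) / circ.R_pv
    return np.array([
        q_mitral - q_aortic,        # lv
        q_tricuspid - q_pulm_valve,  # rv
        q_pv - q_mitral,            # la
        q_sv - q_tricuspid,         # ra
        q_aortic - q_sys,           # sa
        q_sys - q_sv,               # sv
        q_pulm_valve - q_pul,       # pa
        q_pul - q_pv,               # pv
    ])


def test_state_derivative_matches_flow_balance_oracle():
    p = table1()
    rng = np.random.default_rng(42)
    for _ in range(100):
        V = rng.uniform(5.0, 250.0, size=8)
        t = rng.uniform(0.0, 3 * TAU)
        got = cv.state_derivative(t, V, p)
        want = _flow_balance_oracle(t, V, p)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)
        assert abs(got.sum()) < 1e-10 * np.abs(got).max()


def test_state_derivative_initial_state():
    p = table1()
    got = cv.state_derivative(0.0, np.array(p.initial_volumes), p)
    want = _flow_balance_oracle(0.0, np.array(p.initial_volumes), p)
    np.testing.assert_allclose(got, want, rtol=1e-12)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def test_simulate_conserves_total_volume(steady_trajectory):
    total = steady_trajectory.volumes.sum(axis=1)
    assert np.abs(total - 919.996).max() <= 1e-3


def test_simulate_valve_flows_nonnegative(steady_trajectory):
    assert steady_trajectory.flows[:, :4].min() >= 0.0


def test_simulate_reaches_periodic_steady_state(steady_trajectory):
    assert cv.periodicity_residual(steady_trajectory) < 1e-3


def test_zero_duration_returns_initial_state():
    p = table1()
    traj = cv.simulate(p, cv.SimulationConfig(n_cycles=0))
    assert traj.ok
    np.testing.assert_array_equal(traj.volumes[0], p.initial_volumes)
    assert traj.time.shape == (1,)


def test_refinement_stability(base_params):
    """Halving the tolerances leaves the last-cycle waveforms unchanged to
    better than 1e-3 relative L2."""
    a = cv.simulate(base_params, cv.SimulationConfig(rel_tol=1e-6,
                                                     abs_tol=1e-6))
    b = cv.simulate(base_params, cv.SimulationConfig(rel_tol=5e-7,
                                                     abs_tol=5e-7))
    sl = a.extraction_slice()
    num = np.linalg.norm(a.volumes[sl] - b.volumes[sl], axis=0)
    den = np.linalg.norm(a.volumes[sl], axis=0)
    assert (num / den).max() < 1e-3


def test_against_scipy_reference_integrator(base_params):
    """Cross-check the compiled stepper against scipy DOP853 at a tighter
    tolerance over 3 cycles."""
    from scipy.integrate import solve_ivp

    p = base_params
    cfg = cv.SimulationConfig(n_cycles=3)
    ours = cv.simulate(p, cfg)
    times = output_grid(3, cfg.waveform_points)
    ref = solve_ivp(lambda t, y: cv.state_derivative(t, y, p),
                    (0.0, 3 * TAU), np.array(p.initial_volumes),
                    method="DOP853", t_eval=times, rtol=1e-9, atol=1e-9,
                    max_step=TAU / 20)
    assert ref.success
    err = np.linalg.norm(ours.volumes - ref.y.T, axis=0)
    scale = np.linalg.norm(ref.y.T, axis=0)
    assert (err / scale).max() < 1e-4


def test_invalid_timing_is_structured_failure_when_strict(base_params):
    import dataclasses

    bad_lv = dataclasses.replace(base_params.lv, tau_ep=0.1)
    bad = dataclasses.replace(base_params, lv=bad_lv)
    res = cv.simulate(bad, strict_timing=True)
    assert isinstance(res, SimulationFailure)
    assert "timing" in res.reason
    # non-strict: the ordered-branch activation still integrates
    traj = cv.simulate(bad)
    assert traj.ok


def test_diverging_parameters_return_failure_record(base_params):
    import dataclasses

    # a near-zero venous resistance makes the loop too stiff for the step
    # budget: the solve must come back as a failure record, not a partial
    # or garbage trajectory
    circ = dataclasses.replace(base_params.circulation, R_pv=1e-9)
    bad = dataclasses.replace(base_params, circulation=circ)
    res = cv.simulate(bad, cv.SimulationConfig(n_cycles=5, max_steps=50_000))
    assert isinstance(res, SimulationFailure)


# ---------------------------------------------------------------------------
# Periodicity residual on constructed trajectories
# ---------------------------------------------------------------------------

def _constant_trajectory(c_last, c_prev, wp=10):
    cfg = cv.SimulationConfig(n_cycles=2, waveform_points=wp)
    time = output_grid(2, wp)
    vols = np.empty((len(time), 8))
    vols[:wp] = c_prev
    vols[wp:] = c_last
    return Trajectory(time, vols, np.zeros((len(time), 10)),
                      np.zeros((len(time), 6)), table1(), cfg)


def test_periodicity_residual_exact_period_is_zero():
    traj = _constant_trajectory(7.0, 7.0)
    assert cv.periodicity_residual(traj) == 0.0


def test_periodicity_residual_measures_injected_drift():
    # constant cycles at c and c + d give residual d / c exactly
    traj = _constant_trajectory(101.0, 100.0)
    assert cv.periodicity_residual(traj) == pytest.approx(0.01)


# ---------------------------------------------------------------------------
# Parameter container and I/O
# ---------------------------------------------------------------------------

def test_varied_parameter_bookkeeping():
    assert len(cv.PARAM_NAMES) == 38
    assert len(cv.VARIED_PARAMETERS) == 36
    assert "E_shift_lv" not in cv.VARIED_PARAMETERS
    assert "E_shift_rv" not in cv.VARIED_PARAMETERS
    p = table1()
    assert p.total_volume == pytest.approx(919.996)
    assert p.validate() == []


def test_parameter_roundtrip(tmp_path):
    p = table1()
    p.to_json(tmp_path / "p.json")
    q = cv.ModelParameters.from_json(tmp_path / "p.json")
    np.testing.assert_array_equal(p.to_array(), q.to_array())
    p.to_csv(tmp_path / "p.csv")
    r = cv.ModelParameters.from_csv(tmp_path / "p.csv")
    np.testing.assert_array_equal(p.to_array(), r.to_array())
    assert r.initial_volumes == p.initial_volumes


def test_array_roundtrip_and_validation():
    p = table1()
    q = cv.ModelParameters.from_array(p.to_array())
    assert q == p
    import dataclasses
    bad = dataclasses.replace(
        p, circulation=dataclasses.replace(p.circulation, C_sa=-1.0))
    assert any("C_sa" in msg for msg in bad.validate())


def test_trajectory_signal_labels(steady_trajectory):
    for label in ("V_lv", "P_svb", "P_pvb", "Q_s"):
        assert steady_trajectory.signal(label).shape == \
            steady_trajectory.time.shape
    with pytest.raises(KeyError):
        steady_trajectory.signal("X_lv")
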