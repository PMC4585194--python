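"""Integrator behaviour, threshold queries, and oscillation metrics."""

import numpy as np
import pytest

from graftdyn import (
    Trajectory,
    baseline_state,
    find_steady_state,
    integrate,
    make_subsystem_rhs,
    oscillation_metrics,
    time_to_threshold,
)


def _synthetic(g_values, t=None):
    """Trajectory carrying only a graft-function signal (analysis helpers)."""
    g = np.asarray(g_values, dtype=float)
    t = np.arange(g.size, dtype=float) if t is None else np.asarray(t, float)
    y = np.zeros((g.size, 1))
    return Trajectory(t, y, ("D_G",), G=g)


class TestIntegrate:
    def test_baseline_equilibrium_persists(self, params, full_run):
        traj = full_run(0.0, tuple(baseline_state(params)), horizon=1000.0)
        assert np.max(np.abs(traj.y - baseline_state(params))) < 1e-8

    def test_host_injury_below_threshold_resolves(self, params, full_run):
        traj = full_run(0.0, (0, 3, 0, 0.125, 0, 0), horizon=5000.0, graft_present=False)
        assert np.linalg.norm(traj.final_state - baseline_state(params)) < 1e-3

    def test_host_injury_above_threshold_fails(self, params, full_run):
        traj = full_run(0.0, (0, 4, 0, 0.125, 0, 0), horizon=5000.0, graft_present=False)
        assert traj["D"][-1] > 10.0  # elevated-inflammation equilibrium
        assert traj["I"][-1] > 0.3

    def test_input_validation(self, params):
        rhs = make_subsystem_rhs("full", params)
        with pytest.raises(ValueError):
            integrate(rhs, (0, -1, 0, 0.125, 0, 0), 10.0, params)
        with pytest.raises(ValueError):
            integrate(rhs, baseline_state(params), -5.0, params)

    def test_reporting_grid_and_nonnegativity(self, params, full_run):
        traj = full_run(0.0, (0, 3, 0, 0.125, 0, 0), horizon=5000.0, graft_present=False)
        assert traj.t.size == 5001
        assert np.all(np.diff(traj.t) > 0)
        assert np.all(traj.y >= 0)

    def test_trajectory_frame_columns(self, params, full_run):
        traj = full_run(0.1, (0, 2, 1, 0.125, 0, 0))
        frame = traj.to_frame()
        assert list(frame.columns) == ["t", "I", "D", "D_G", "A", "T_P", "T_A", "G"]
        assert len(frame) == traj.t.size


class TestFindSteadyState:
    def test_baseline_converges_in_place(self, params):
        rhs = make_subsystem_rhs("full", params)
        ss = find_steady_state(rhs, baseline_state(params), params, horizon=500.0)
        assert ss.converged
        np.testing.assert_allclose(ss.state, baseline_state(params), atol=1e-9)

    def test_limit_cycle_reports_nonconverged(self, params):
        p = params.replace(alpha=0.4)
        rhs = make_subsystem_rhs("full", p, alpha=0.4)
        ss = find_steady_state(rhs, (0, 0, 1.9, 0.125, 0, 0), p, horizon=10_000.0)
        assert not ss.converged


class TestTimeToThreshold:
    def test_never_crossing_returns_none(self):
        traj = _synthetic(np.full(100, 0.9))
        assert time_to_threshold(traj, 0.5) is None

    def test_linear_interpolation_between_grid_points(self):
        traj = _synthetic([1.0, 0.8, 0.4, 0.2])
        # G crosses 0.5 a quarter of the way from t=1 to t=2
        assert time_to_threshold(traj, 0.5) == pytest.approx(1.75)

    def test_crossing_at_start(self):
        traj = _synthetic([0.1, 0.05])
        assert time_to_threshold(traj, 0.2) == 0.0


class TestOscillationMetrics:
    def test_steady_signal_not_sustained(self):
        traj = _synthetic(np.full(400, 0.97))
        om = oscillation_metrics(traj)
        assert not om.sustained
        assert om.g_min == om.g_max == pytest.approx(0.97)

    def test_sustained_cycle_detected_with_period(self):
        t = np.arange(4000, dtype=float)
        g = 0.7 + 0.25 * np.sin(2 * np.pi * t / 200.0)
        om = oscillation_metrics(_synthetic(g, t))
        assert om.sustained
        assert om.g_min == pytest.approx(0.45, abs=1e-3)
        assert om.g_max == pytest.approx(0.95, abs=1e-3)
        assert om.period_estimate == pytest.approx(200.0, rel=0.02)

    def test_damped_ring_not_sustained(self):
        t = np.arange(4000, dtype=float)
        g = 0.9 + 0.1 * np.exp(-t / 400.0) * np.sin(2 * np.pi * t / 200.0)
        assert not oscillation_metrics(_synthetic(g, t)).sustained

    def test_window_too_short_is_an_error(self):
        with pytest.raises(ValueError):
            oscillation_metrics(_synthetic(np.linspace(1, 0.9, 20)))


def test_solver_tolerance_independence(params, full_run):
    """Halving tolerances moves the limit-cycle extrema by < 0.1 pp."""
    p = params.replace(alpha=0.4)
    rhs = make_subsystem_rhs("full", p, alpha=0.4)
    loose = full_run(0.4, (0, 0, 1.9, 0.125, 0, 0))
    tight = integrate(rhs, (0, 0, 1.9, 0.125, 0, 0), 10_000.0, p, reltol=5e-10, abstol=5e-13)
    om_l, om_t = oscillation_metrics(loose), oscillation_metrics(tight)
    assert abs(om_l.g_min - om_t.g_min) < 1e-3
    assert abs(om_l.g_max - om_t.g_max) < 1e-3
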