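"""Numerical integration and trajectory analysis.

The sixth-power Hill terms make the vector field switch-like, so the
default integrator is LSODA (adaptive, stiffness-switching) at tight
tolerances (rtol 1e-9, atol 1e-12).  Output is reported on a uniform grid
of at most 1 h spacing; round-off negatives are clipped to zero before the
right-hand side is evaluated, keeping the nonnegative orthant invariant in
practice as it is in exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .model import graft_function
from .params import ModelParameters

__all__ = [
    "Trajectory",
    "OscillationMetrics",
    "SteadyState",
    "IntegrationError",
    "integrate",
    "find_steady_state",
    "time_to_threshold",
    "oscillation_metrics",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last time reached before breakdown."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Time-ordered solution of one model run.

    ``y`` has one row per time point in the column order ``columns``;
    ``G`` holds the derived graft functionality whenever the run tracks
    graft damage with a graft present.
    """

    t: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    G: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.t.size, len(self.columns)):
            raise ValueError("states shape does not match times/columns")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "G":
            if self.G is None:
                raise KeyError("trajectory has no graft-function column")
            return self.G
        return self.y[:, self.columns.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=list(self.columns))
        frame.insert(0, "t", self.t)
        if self.G is not None:
            frame["G"] = self.G
        return frame


@dataclass
class OscillationMetrics:
    """Attractor summary of the graft-function signal over a trailing window."""

    g_min: float
    g_max: float
    sustained: bool
    period_estimate: float | None = None

    @property
    def amplitude(self) -> float:
        return self.g_max - self.g_min


@dataclass
class SteadyState:
    state: np.ndarray
    converged: bool
    residual: float


def _clipping(rhs: Callable) -> Callable:
    def wrapped(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite state at t={t}: {y}")
        return rhs(t, np.maximum(y, 0.0))

    return wrapped


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    initial: Sequence[float],
    t_end: float,
    params: ModelParameters | None = None,
    *,
    reltol: float = 1e-9,
    abstol: float = 1e-12,
    method: str = "LSODA",
    max_step: float | None = None,
    grid_dt: float = 1.0,
    columns: Sequence[str] | None = None,
    graft_present: bool = True,
    metadata: Mapping | None = None,
) -> Trajectory:
    """Integrate ``rhs`` from ``initial`` to ``t_end`` on a uniform report grid.

    ``columns`` names the state components (taken from ``rhs.columns`` if the
    callable carries them); graft functionality is derived from the D_G
    column when ``params`` is given and a graft is present.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.asarray(initial, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    if columns is None:
        columns = getattr(rhs, "columns", tuple(f"y{i}" for i in range(y0.size)))
    if len(columns) != y0.size:
        raise ValueError("columns do not match the state dimension")

    n_grid = int(np.ceil(t_end / grid_dt))
    t_eval = np.linspace(0.0, t_end, n_grid + 1)
    sol = solve_ivp(
        _clipping(rhs),
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=reltol,
        atol=abstol,
        max_step=np.inf if max_step is None else max_step,
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"integration failed at t={last:.3f}: {sol.message}", last)

    states = np.maximum(sol.y.T, 0.0)  # clip solver round-off negatives
    g = None
    if params is not None and graft_present and "D_G" in columns:
        g = graft_function(states[:, list(columns).index("D_G")], params)

    meta = dict(metadata or {})
    meta.setdefault("solver", {"method": method, "reltol": reltol, "abstol": abstol})
    meta.setdefault("graft_present", graft_present)
    return Trajectory(sol.t, states, tuple(columns), G=g, metadata=meta)


def find_steady_state(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    initial: Sequence[float],
    params: ModelParameters | None = None,
    horizon: float = 10_000.0,
    *,
    residual_tol: float = 1e-10,
    drift_tol: float = 1e-6,
    **integrate_kwargs,
) -> SteadyState:
    """Relax toward an attractor and Newton-polish the endpoint.

    ``converged`` is True only if the trailing 10% of the trajectory is
    stationary (component drift below ``drift_tol``) and the polished point
    has residual below ``residual_tol``; otherwise the attractor is
    non-stationary (a limit cycle) and the raw endpoint is returned.
    """
    traj = integrate(rhs, initial, horizon, params, **integrate_kwargs)
    tail = traj.y[int(0.9 * traj.t.size):]
    drift = float(np.max(tail.max(axis=0) - tail.min(axis=0)))

    endpoint = traj.final_state
    if drift >= drift_tol:
        return SteadyState(endpoint, False, float(np.linalg.norm(rhs(0.0, endpoint))))

    sol = root(lambda y: rhs(0.0, np.maximum(y, 0.0)), endpoint, method="hybr", tol=1e-13)
    polished = np.maximum(sol.x, 0.0)
    residual = float(np.linalg.norm(rhs(0.0, polished)))
    if residual < residual_tol and np.linalg.norm(polished - endpoint) < 1e-2 * (
        1.0 + np.linalg.norm(endpoint)
    ):
        return SteadyState(polished, True, residual)
    return SteadyState(endpoint, False, float(np.linalg.norm(rhs(0.0, endpoint))))


def time_to_threshold(traj: Trajectory, g_level: float) -> float | None:
    """Earliest time at which graft functionality drops to ``g_level``.

    Linear interpolation between report-grid points; None if the level is
    never crossed.
    """
    if traj.G is None:
        raise ValueError("trajectory has no graft-function values")
    g = traj.G
    below = np.nonzero(g <= g_level)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(traj.t[0])
    t0, t1 = traj.t[i - 1], traj.t[i]
    g0, g1 = g[i - 1], g[i]
    if g1 == g0:
        return float(t1)
    return float(t0 + (g0 - g_level) / (g0 - g1) * (t1 - t0))


def oscillation_metrics(
    traj: Trajectory,
    window_fraction: float = 0.25,
    *,
    amplitude_ratio: float = 0.9,
    min_amplitude: float = 0.01,
) -> OscillationMetrics:
    """Classify the trailing graft-function signal as sustained or damped.

    The trajectory is split into a trailing window (default the last quarter
    of the run) and the window of equal length preceding it.  Oscillation is
    ``sustained`` when the trailing peak-to-trough amplitude is at least
    ``amplitude_ratio`` of the preceding window's amplitude and exceeds
    ``min_amplitude``; a shrinking amplitude indicates damped (resolving)
    oscillations.
    """
    if traj.G is None:
        raise ValueError("trajectory has no graft-function values")
    n = traj.t.size
    w = int(np.floor(window_fraction * n))
    if w < 10 or 2 * w > n:
        raise ValueError("trailing window too short to assess oscillation")
    last = traj.G[n - w:]
    prev = traj.G[n - 2 * w: n - w]
    amp_last = float(last.max() - last.min())
    amp_prev = float(prev.max() - prev.min())
    sustained = amp_last >= amplitude_ratio * amp_prev and amp_last > min_amplitude

    period = None
    if sustained:
        peaks, _ = find_peaks(last, prominence=0.25 * amp_last)
        if peaks.size >= 2:
            period = float(np.mean(np.diff(traj.t[n - w:][peaks])))
    return OscillationMetrics(
        g_min=float(last.min()), g_max=float(last.max()), sustained=sustained,
        period_estimate=period,
    )
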