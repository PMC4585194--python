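"""Equilibrium location, linear stability, and one-parameter scans.

Equilibria are roots of the right-hand side found by deterministic
multi-start root-finding (a Halton low-discrepancy start grid, so the
inventory is reproducible without a seed), polished to residual < 1e-10 and
classified by the eigenvalues of a finite-difference Jacobian.  One-sided
differences are used at the boundary of the nonnegative orthant so the
vector field is never evaluated at negative states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .dynamics import Trajectory, integrate
from .model import graft_function, hill, suppress
from .params import ModelParameters
from .subsystems import rhs_dg_tp, rhs_dtotal_i

__all__ = [
    "EquilibriumReport",
    "ScanResult",
    "numeric_jacobian",
    "classify_eigenvalues",
    "find_equilibria",
    "scan_constant_A_bistability",
    "scan_alpha_origin_stability",
    "basin_threshold",
]

MARGINAL_TOL = 1e-8  # |Re(lambda)| below this is reported as marginal


@dataclass
class EquilibriumReport:
    location: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # stable_node, stable_spiral, saddle, unstable_node, unstable_spiral, marginal
    residual: float

    @property
    def stable(self) -> bool:
        return self.classification in ("stable_node", "stable_spiral")


@dataclass
class ScanResult:
    """One-parameter scan summary: per-grid-point summaries plus detected thresholds."""

    parameter: str
    grid: np.ndarray
    summary: list[dict]
    thresholds: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": [float(v) for v in self.grid],
            "summary": self.summary,
            "thresholds": [float(v) for v in self.thresholds],
        }


def numeric_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian with one-sided steps at the x >= 0 boundary."""
    x = np.asarray(x, dtype=float)
    n = x.size
    jac = np.empty((n, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(x[j]))
        if x[j] - h < 0.0:
            e = np.zeros(n)
            e[j] = h
            jac[:, j] = (f(x + e) - f(x)) / h
        else:
            e = np.zeros(n)
            e[j] = h
            jac[:, j] = (f(x + e) - f(x - e)) / (2.0 * h)
    return jac


def classify_eigenvalues(eigenvalues: np.ndarray) -> str:
    re = np.real(eigenvalues)
    im = np.imag(eigenvalues)
    if np.max(re) > MARGINAL_TOL and np.min(re) < -MARGINAL_TOL:
        return "saddle"
    if abs(np.max(re)) <= MARGINAL_TOL:
        return "marginal"
    spiral = bool(np.any(np.abs(im) > MARGINAL_TOL))
    if np.max(re) < 0:
        return "stable_spiral" if spiral else "stable_node"
    return "unstable_spiral" if spiral else "unstable_node"


def _report(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray) -> EquilibriumReport:
    jac = numeric_jacobian(f, x)
    eig = np.linalg.eigvals(jac)
    return EquilibriumReport(
        location=x,
        eigenvalues=eig,
        classification=classify_eigenvalues(eig),
        residual=float(np.linalg.norm(f(x))),
    )


def find_equilibria(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 100,
    *,
    residual_tol: float = 1e-10,
    dedup_tol: float = 1e-6,
) -> list[EquilibriumReport]:
    """Locate all equilibria of ``rhs`` inside ``bounds``.

    Starts are a deterministic Halton grid over the box plus the origin and
    the box corners.  Roots outside the box (with a small pad) or with
    residual above ``residual_tol`` are discarded; survivors are
    deduplicated at pairwise distance ``dedup_tol`` and classified.
    """
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    dim = len(bounds)
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])

    def f(x: np.ndarray) -> np.ndarray:
        return np.asarray(rhs(0.0, np.maximum(x, 0.0)), dtype=float)

    starts = [lows.copy()]
    halton = qmc.Halton(d=dim, scramble=False)
    u = halton.random(n_starts)
    starts.extend(lows + (highs - lows) * u)
    # second layer biased toward the origin corner, where equilibria of the
    # switch-like Hill terms cluster at small state values
    starts.extend(lows + (highs - lows) * u**3)
    # box corners
    for mask in range(1, 2**dim):
        corner = lows.copy()
        for j in range(dim):
            if mask >> j & 1:
                corner[j] = highs[j]
        starts.append(corner)

    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(f, x0, method="hybr", tol=1e-13)
        x = np.maximum(sol.x, 0.0)
        if np.linalg.norm(f(x)) > residual_tol:
            continue
        if np.any(x < lows - 1e-6) or np.any(x > highs + 1e-6):
            continue
        if any(np.linalg.norm(x - r) <= dedup_tol for r in roots):
            continue
        roots.append(x)

    roots.sort(key=lambda r: float(np.linalg.norm(r)))
    return [_report(f, r) for r in roots]


# ---------------------------------------------------------------------------
# constant-A bistability of the merged damage / innate subsystem


def _count_dtotal_equilibria(
    params: ModelParameters,
    fixed_A: float,
    include_graft_term: bool = False,
    n_grid: int = 8001,
) -> int:
    """Count equilibria of the D_Total/I subsystem at a constant A level.

    The two-variable equilibrium problem reduces to one dimension: the
    damage nullcline gives D_Total as an explicit (or, with the graft term,
    strictly monotone implicit) function of I, which substituted into the
    activation nullcline leaves a scalar root count on I in (0, s_ir/mu_i].
    The origin is always an equilibrium and is counted separately.
    """
    p = params
    s = 1.0 / (1.0 + (fixed_A / p.a_inf) ** 2)
    i = np.linspace(0.0, p.cap_i, n_grid)[1:]
    f_i = hill(i * s, p.x_di)
    if not include_graft_term:
        d = (p.k_di / p.mu_d) * f_i
    else:
        d_max = (p.k_di + p.k_dig) / p.mu_d
        d = np.empty_like(f_i)
        for j, fj in enumerate(f_i):
            # mu_d * D - (k_di + k_dig * G(D)) * f = 0 is strictly increasing in D
            d[j] = brentq(
                lambda dd, fj=fj: p.mu_d * dd - (p.k_di + p.k_dig * graft_function(dd, p)) * fj,
                0.0,
                d_max,
                xtol=1e-12,
            )
    r = (p.k_id * d + p.k_ii * i) * s
    g = p.s_ir * r / (p.mu_ir + r) - p.mu_i * i
    signs = np.sign(g)
    crossings = int(np.sum(signs[:-1] * signs[1:] < 0)) + int(np.sum(signs == 0))
    return 1 + crossings


def scan_constant_A_bistability(
    params: ModelParameters | None = None,
    *,
    a_lo: float = 0.0,
    a_hi: float = 1.0,
    grid_step: float = 1e-4,
    refine_tol: float = 1e-5,
    include_graft_term: bool = False,
) -> ScanResult:
    """Sweep a constant anti-inflammatory level and find where bistability is lost.

    For small A the merged damage/innate subsystem has three equilibria
    (healthy, saddle, elevated); above a critical A the saddle-node
    collision removes the unhealthy pair and only the healthy state
    remains.  The largest three-equilibria grid point is refined by
    bisection to ``refine_tol``.
    """
    p = params if params is not None else ModelParameters()
    grid = np.arange(a_lo, a_hi + 0.5 * grid_step, grid_step)
    counts = [
        _count_dtotal_equilibria(p, a, include_graft_term=include_graft_term) for a in grid
    ]
    summary = [{"fixed_A": float(a), "n_equilibria": c} for a, c in zip(grid, counts)]

    thresholds: list[float] = []
    idx = [k for k, c in enumerate(counts) if c >= 3]
    if idx and idx[-1] + 1 < len(grid):
        lo, hi = float(grid[idx[-1]]), float(grid[idx[-1] + 1])
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if _count_dtotal_equilibria(p, mid, include_graft_term=include_graft_term) >= 3:
                lo = mid
            else:
                hi = mid
        thresholds.append(0.5 * (lo + hi))
    return ScanResult("fixed_A", grid, summary, thresholds)


# ---------------------------------------------------------------------------
# alpha scan of the graft-damage / T-cell subsystem origin


def scan_alpha_origin_stability(
    params: ModelParameters | None = None,
    *,
    alpha_lo: float = 0.0,
    alpha_hi: float = 0.2,
    grid_step: float = 0.001,
) -> ScanResult:
    """Stability of the origin of the D_G/T_P subsystem across mismatch levels.

    The largest grid alpha at which every eigenvalue real part is strictly
    negative is reported as the threshold (the analytic boundary is
    alpha* = mu_tp * mu_t0 / (k_tpt0g * s_t0)); eigenvalues within the
    marginal band are not counted as stable.
    """
    p = params if params is not None else ModelParameters()
    n = int(round((alpha_hi - alpha_lo) / grid_step))
    grid = alpha_lo + grid_step * np.arange(n + 1)
    summary = []
    last_stable = None
    for a in grid:
        def f(x, a=a):
            return rhs_dg_tp(0.0, np.maximum(x, 0.0), p, float(a))

        jac = numeric_jacobian(f, np.zeros(2))
        eig = np.linalg.eigvals(jac)
        cls = classify_eigenvalues(eig)
        stable = float(np.max(np.real(eig))) < -MARGINAL_TOL
        if stable:
            last_stable = float(a)
        summary.append(
            {"alpha": float(a), "max_re": float(np.max(np.real(eig))), "classification": cls}
        )
    thresholds = [last_stable] if last_stable is not None else []
    return ScanResult("alpha", grid, summary, thresholds)


# ---------------------------------------------------------------------------
# basin-of-attraction thresholds


def basin_threshold(
    trajectory_for: Callable[[float], Trajectory],
    classifier: Callable[[Trajectory], str],
    lo: float,
    hi: float,
    grid_step: float = 0.001,
) -> float:
    """Largest value on a ``grid_step`` grid whose trajectory recovers.

    ``trajectory_for(v)`` runs the scenario with the varied initial
    component set to ``v``; ``classifier`` must return "recover" or "fail".
    Assumes the basin is monotone along this ray (verified at the bracket
    endpoints), brackets the boundary by bisection to below ``grid_step``
    and snaps down to the grid.
    """

    def classify(v: float) -> str:
        label = classifier(trajectory_for(v))
        if label not in ("recover", "fail"):
            raise ValueError(f"ambiguous classification {label!r} at value {v}")
        return label

    if classify(lo) != "recover":
        raise ValueError(f"lower bracket {lo} does not recover")
    if classify(hi) != "fail":
        raise ValueError(f"upper bracket {hi} does not fail")
    while hi - lo > 0.5 * grid_step:
        mid = 0.5 * (lo + hi)
        if classify(mid) == "recover":
            lo = mid
        else:
            hi = mid
    return float(np.floor(lo / grid_step + 1e-9) * grid_step)
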