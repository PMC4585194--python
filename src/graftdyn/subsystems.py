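"""Reduced subsystems of the full model.

The full six-variable system was built bottom-up by analysing small groups
of interacting variables ("subsystem modelling"):

* ``dtotal_i``  — merged host+graft damage D_Total driven by innate
  activation I; the bistable core (healthy vs. elevated-damage state).
* ``i_tp``      — innate components and pro-inflammatory T cells without any
  damage feedback; calibrates the mutual recruitment rates so that neither
  population can sustain the other on its own.
* ``dg_tp``     — graft damage and alloreactive T cells; the mismatch factor
  alpha moves the origin through a stability boundary and a damped-
  oscillation (stable-spiral) regime appears above it.
* ``dg_tp_i``   — graft damage, T cells and innate activation; bistable even
  at alpha = 0, with a small basin of graft recovery.

Each right-hand side keeps exactly the terms of its reduction, with the
quasi-steady-state T_0 expression evaluated with the omitted variables at
zero, so that the printed thresholds and equilibria of the reduced analyses
are reproducible.  ``fixed_A`` treats the anti-inflammatory level as a
constant parameter in the inhibition factors (0 disables inhibition, which
is the form the merged-damage analysis uses).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .model import STATE_VARS, graft_function, hill, make_full_rhs, suppress
from .params import ModelParameters

__all__ = [
    "SUBSYSTEM_VARS",
    "rhs_dtotal_i",
    "rhs_i_tp",
    "rhs_dg_tp",
    "rhs_dg_tp_i",
    "make_subsystem_rhs",
    "origin_jacobian_i_tp",
]

#: State-variable names per subsystem id, in right-hand-side order.
SUBSYSTEM_VARS: dict[str, tuple[str, ...]] = {
    "dtotal_i": ("I", "D_Total"),
    "i_tp": ("I", "T_P"),
    "dg_tp": ("D_G", "T_P"),
    "dg_tp_i": ("I", "D_G", "T_P"),
    "full": STATE_VARS,
}


def rhs_dtotal_i(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    *,
    fixed_A: float = 0.0,
    include_graft_term: bool = False,
) -> np.ndarray:
    """Merged damage / innate activation subsystem, state (I, D_Total).

    With ``fixed_A`` > 0 the constant anti-inflammatory level divides both
    the activation drive and the Hill argument; with ``include_graft_term``
    the damage gain acquires the graft-scaled contribution
    k_dig * G(D_Total) * f(I), which vanishes at the elevated equilibrium
    because G is already ~0 there.
    """
    if fixed_A < 0:
        raise ValueError("fixed_A must be nonnegative")
    i, d_tot = np.asarray(state, dtype=float)
    p = params
    r = suppress(p.k_id * d_tot + p.k_ii * i, fixed_A, p.a_inf)
    di = p.s_ir * r / (p.mu_ir + r) - p.mu_i * i
    f_i = hill(suppress(i, fixed_A, p.a_inf), p.x_di)
    dd = p.k_di * f_i - p.mu_d * d_tot
    if include_graft_term:
        dd += p.k_dig * graft_function(d_tot, p) * f_i
    return np.array([di, dd])


def rhs_i_tp(t: float, state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Innate / pro-inflammatory T-cell subsystem, state (I, T_P).

    No damage variables: activation is driven purely by the mutual
    recruitment terms k_ii, k_itp and k_tpi, with T_0 in quasi-steady state.
    At the calibrated rates (0.008) the origin is stable; at 0.01 it is not,
    which is exactly the property the calibration pinned down.
    """
    i, t_p = np.asarray(state, dtype=float)
    p = params
    drive = p.k_ii * i + p.k_itp * t_p
    di = p.s_ir * drive / (p.mu_ir + drive) - p.mu_i * i
    t0 = p.s_t0 / (p.mu_t0 + p.k_tpi * i)
    dt_p = p.k_tpi * t0 * i - p.mu_tp * t_p
    return np.array([di, dt_p])


def origin_jacobian_i_tp(params: ModelParameters) -> np.ndarray:
    """Closed-form Jacobian of the I/T_P subsystem at the origin (test oracle)."""
    p = params
    return np.array(
        [
            [p.s_ir * p.k_ii / p.mu_ir - p.mu_i, p.s_ir * p.k_itp / p.mu_ir],
            [p.k_tpi * p.s_t0 / p.mu_t0, -p.mu_tp],
        ]
    )


def rhs_dg_tp(
    t: float, state: np.ndarray, params: ModelParameters, alpha: float | None = None
) -> np.ndarray:
    """Graft damage / alloreactive T-cell subsystem, state (D_G, T_P).

    All damage is T-cell mediated and alpha-scaled.  The origin loses
    stability when alpha * k_tpt0g * (s_t0/mu_t0) exceeds mu_tp
    (alpha* = 0.075 at default rates); just above the boundary a positive
    stable-spiral equilibrium carries damped oscillations.
    """
    d_g, t_p = np.asarray(state, dtype=float)
    p = params
    a = p.alpha if alpha is None else alpha
    if not 0.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    g = graft_function(d_g, p)
    dd_g = -p.mu_d * d_g + a * p.k_dgtp * g * hill(t_p, p.x_dgtp)
    t0 = p.s_t0 / (p.mu_t0 + a * p.k_tpt0g * t_p * g)
    dt_p = a * p.k_tpt0g * t0 * t_p * g - p.mu_tp * t_p
    return np.array([dd_g, dt_p])


def rhs_dg_tp_i(
    t: float, state: np.ndarray, params: ModelParameters, alpha: float | None = None
) -> np.ndarray:
    """Graft damage / T-cell / innate subsystem, state (I, D_G, T_P).

    Adds innate activation (driven here by graft DAMPs only) to the
    alloreactive loop.  Bistable even at alpha = 0: initial graft damage
    above ~0.095 tips the system into the elevated failure state with
    ~13% residual graft function.
    """
    i, d_g, t_p = np.asarray(state, dtype=float)
    p = params
    a = p.alpha if alpha is None else alpha
    if not 0.0 <= a <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    g = graft_function(d_g, p)
    r1 = p.k_id * d_g + p.k_ii * i + p.k_itp * t_p
    di = p.s_ir * r1 / (p.mu_ir + r1) - p.mu_i * i
    f_i = hill(i, p.x_di)
    dd_g = -p.mu_d * d_g + p.k_dgig * g * f_i + a * p.k_dgtp * g * hill(t_p, p.x_dgtp)
    t0 = p.s_t0 / (p.mu_t0 + p.k_tpi * i + a * p.k_tpig * i * g + a * p.k_tpt0g * t_p * g)
    dt_p = p.k_tpi * t0 * i + a * p.k_tpig * t0 * i * g + a * p.k_tpt0g * t0 * t_p * g - p.mu_tp * t_p
    return np.array([di, dd_g, dt_p])


def make_subsystem_rhs(
    name: str,
    params: ModelParameters,
    *,
    alpha: float | None = None,
    graft_present: bool = True,
    **kwargs,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind a subsystem (or the full model) into an ``f(t, y)`` callable.

    ``alpha`` overrides ``params.alpha`` where the subsystem takes it;
    extra keyword arguments (``fixed_A``, ``include_graft_term``) are passed
    through to ``rhs_dtotal_i``.
    """
    if name == "full":
        p = params if alpha is None else params.replace(alpha=alpha)
        return make_full_rhs(p, graft_present=graft_present)
    if name == "dtotal_i":
        def rhs(t, y):
            return rhs_dtotal_i(t, y, params, **kwargs)
    elif name == "i_tp":
        def rhs(t, y):
            return rhs_i_tp(t, y, params)
    elif name == "dg_tp":
        def rhs(t, y):
            return rhs_dg_tp(t, y, params, alpha)
    elif name == "dg_tp_i":
        def rhs(t, y):
            return rhs_dg_tp_i(t, y, params, alpha)
    else:
        raise ValueError(f"unknown subsystem {name!r}; choose from {sorted(SUBSYSTEM_VARS)}")
    rhs.columns = SUBSYSTEM_VARS[name]  # type: ignore[attr-defined]
    return rhs
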