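"""Core of the six-variable transplant-immune ODE model.

State vector (in this fixed order):

    I    activated innate pro-inflammatory components (macrophages, PMN, NK, TNF-alpha, ...)
    D    host tissue damage (DAMP release proxy)
    D_G  graft tissue damage
    A    anti-inflammatory mediators (IL-10, TGF-beta1, M2 macrophages, ...)
    T_P  pro-inflammatory T cells (TH1/TH17/gamma-delta)
    T_A  anti-inflammatory T cells (Treg/TH2)

Two fast pools are eliminated by quasi-steady-state (QSS) reduction: the
resting innate pool I_R and the inactive memory T-cell pool T_0; their
instantaneous algebraic equilibria enter the right-hand side as auxiliary
variables.  Graft health G is a monotone decreasing transform of D_G
(1 = 100% function).  The mismatch factor ``alpha`` scales every
allo-recognition term; with ``alpha = 0`` the graft is antigenically
identical to the host and only DAMP-driven damage remains.

Time is measured in hours throughout; all state variables carry arbitrary
model units.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .params import ModelParameters

__all__ = [
    "STATE_VARS",
    "baseline_state",
    "hill",
    "suppress",
    "graft_function",
    "qss_ir",
    "qss_t0",
    "full_rhs",
    "make_full_rhs",
]

#: Order of the dynamic variables in every 6-vector used by this package.
STATE_VARS: tuple[str, ...] = ("I", "D", "D_G", "A", "T_P", "T_A")

HILL_EXPONENT = 6  # fixed; chosen so the healthy state has a realistic basin


def baseline_state(params: ModelParameters | None = None) -> np.ndarray:
    """Unperturbed healthy equilibrium: all zero except A = s_a/mu_a."""
    p = params if params is not None else ModelParameters()
    y = np.zeros(6)
    y[3] = p.baseline_a
    return y


def _check_nonneg(name: str, x) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be nonnegative")


def hill(x, x_half: float):
    """Sixth-order Hill saturation x^6 / (x^6 + x_half^6).

    Strictly increasing on x >= 0, equal to 1/2 at ``x_half`` and
    approaching 1 as x grows.  The steep sixth-power form makes damage
    production effectively switch-like around the half-max level.
    """
    _check_nonneg("x", x)
    if x_half <= 0:
        raise ValueError("x_half must be positive")
    xr = np.asarray(x, dtype=float) / x_half
    x6 = xr**HILL_EXPONENT
    out = x6 / (x6 + 1.0)
    return out if out.ndim else float(out)


def suppress(x, y, scale: float):
    """Anti-inflammatory inhibition x / (1 + (y/scale)^2).

    Divides a pro-inflammatory drive ``x`` by a quadratic function of the
    inhibitor level ``y`` (A or T_A); equals ``x`` when no inhibitor is
    present and halves it at ``y = scale``.
    """
    _check_nonneg("x", x)
    _check_nonneg("y", y)
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = np.asarray(x, dtype=float) / (1.0 + (np.asarray(y, dtype=float) / scale) ** 2)
    return out if out.ndim else float(out)


def graft_function(d_g, params: ModelParameters | None = None):
    """Graft health G in (0, 1] as a function of graft damage D_G.

    G = 1 - (1 - exp(-D_G/x_gdg)) / (1 + k_gdg * exp(-D_G/x_gdg))

    G(0) = 1 (100% function), strictly decreasing, and G -> 0 as damage
    grows without bound.  With the default shape (k_gdg = 10, x_gdg = 0.5)
    damage 1.8 maps to 24% and 1.9 to 20% function.
    """
    _check_nonneg("d_g", d_g)
    p = params if params is not None else ModelParameters()
    e = np.exp(-np.asarray(d_g, dtype=float) / p.x_gdg)
    out = 1.0 - (1.0 - e) / (1.0 + p.k_gdg * e)
    return out if out.ndim else float(out)


def qss_ir(state: np.ndarray, params: ModelParameters) -> float:
    """Quasi-steady-state resting innate pool I_R.

    I_R = s_ir / (mu_ir + k_id (D + D_G) + k_ii I + k_itp T_P): the faster
    the pool is consumed by activation, the lower it sits.  At baseline it
    equals s_ir/mu_ir.
    """
    p = params
    i, d, d_g, _, t_p, _ = state
    return p.s_ir / (p.mu_ir + p.k_id * (d + d_g) + p.k_ii * i + p.k_itp * t_p)


def qss_t0(state: np.ndarray, params: ModelParameters, graft_present: bool = True) -> float:
    """Quasi-steady-state inactive memory T-cell pool T_0.

    Balances the constant source s_t0 against decay and the consumption by
    every T-cell activation route (innate-driven, allo-driven, and the
    regulatory route via A).  At baseline it equals s_t0/mu_t0.  When no
    graft is present the graft-function factor G is 0 and every
    alpha-scaled route vanishes.
    """
    p = params
    i, _, d_g, a, t_p, t_a = state
    g = graft_function(d_g, p) if graft_present else 0.0
    consumption = (
        p.mu_t0
        + p.k_tpi * i
        + p.alpha * p.k_tpig * i * g
        + p.k_taia * a * i
        + p.alpha * p.k_tpt0g * t_p * g
    )
    denom = p.alpha * p.k_tat0g * t_a * g + consumption * (1.0 + t_a)
    return p.s_t0 * (1.0 + t_a) / denom


def full_rhs(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    graft_present: bool = True,
) -> np.ndarray:
    """Right-hand side of the full six-variable model.

    Returns (dI/dt, dD/dt, dD_G/dt, dA/dt, dT_P/dt, dT_A/dt) at ``state``.
    When ``graft_present`` is False the graft-damage equation is frozen at
    zero and every graft-bearing term is dropped (G = 0), modelling the
    surgical/IRI insult without an implanted organ.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y}")
    i, d, d_g, a, t_p, t_a = y
    p = params

    g = graft_function(d_g, p) if graft_present else 0.0

    # innate activation, inhibited by A
    r = suppress(p.k_id * (d + d_g) + p.k_ii * i + p.k_itp * t_p, a, p.a_inf)
    di = p.s_ir * r / (p.mu_ir + r) - p.mu_i * i

    # damage production is switch-like in the (A-inhibited) innate level
    f_i = hill(suppress(i, a, p.a_inf), p.x_di)
    dd = p.k_di * f_i - p.mu_d * d

    if graft_present:
        f_tp = hill(suppress(t_p, t_a, p.b_inf), p.x_dgtp)
        dd_g = -p.mu_d * d_g + p.k_dgig * g * f_i + p.alpha * p.k_dgtp * g * f_tp
    else:
        dd_g = 0.0

    # anti-inflammatory induction saturates in the combined damage signal
    x = suppress(i + p.k_aid * d, a, p.a_inf)
    da = -p.mu_a * a + p.s_a + p.k_ai * x / (1.0 + x) + p.k_ata * t_a

    t0 = qss_t0(y, p, graft_present)
    inh_ta = 1.0 + (t_a / p.b_inf) ** 2
    dt_p = (
        p.k_tpi * t0 * i + p.alpha * p.k_tpig * t0 * i * g + p.alpha * p.k_tpt0g * t0 * t_p * g
    ) / inh_ta - p.mu_tp * t_p

    dt_a = (
        p.k_taia * t0 * i * a
        + p.alpha * p.k_tat0g * t0 * g * t_a / (1.0 + t_a)
        - p.mu_ta * t_a
    )

    return np.array([di, dd, dd_g, da, dt_p, dt_a])


def make_full_rhs(
    params: ModelParameters, graft_present: bool = True
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind parameters into a ``f(t, y)`` callable for the integrator."""

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return full_rhs(t, y, params, graft_present)

    rhs.columns = STATE_VARS  # type: ignore[attr-defined]
    return rhs
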