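"""Fast-information-spread limit and the analytic suppression threshold.

When information spreads much faster than the disease (``alpha_T, alpha_D
-> infinity``) the awareness distribution collapses: as soon as the first
infected individual refreshes to level 0, every trusting individual holds
level-1 information while the distrusting population stays in the unaware
reservoir.  The model then reduces to five compartments — trusting
susceptibles/infected at levels 1 and 0/1, and distrusting mass in the
reservoir.  Assuming the infected sub-groups are metastable at the phase
boundary (dI/dt = 0 with quasi-stationary ratios between I_0, I_1 and
I_inf) yields a quadratic in ``x = 1 - rho`` whose positive root gives the
critical intervention effectiveness ``rho_c(d)``.  The threshold exists
only below the critical distrusting density ``d_M = sigma/beta = 1/R_0``;
above it no level of protection can suppress the outbreak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParams

__all__ = [
    "FastLimitState",
    "fast_limit_rhs",
    "integrate_fast_limit",
    "quasi_steady_ratios",
    "critical_quadratic_coeffs",
    "critical_rho_analytic",
    "critical_density",
    "critical_curve",
    "CriticalRho",
    "CriticalCurve",
]


@dataclass
class FastLimitState:
    """Compartments of the reduced model.

    ``S1``/``I1`` are trusting susceptibles/infected at awareness level 1,
    ``I0`` trusting infected at level 0 (fresh information; non-infectious),
    ``S_inf``/``I_inf`` the unaware distrusting mass.
    """

    S1: float
    S_inf: float
    I0: float
    I1: float
    I_inf: float

    def to_array(self) -> np.ndarray:
        return np.array([self.S1, self.S_inf, self.I0, self.I1, self.I_inf])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FastLimitState":
        return cls(*map(float, y))


def fast_limit_rhs(state, params: ModelParams) -> np.ndarray:
    """Right-hand side of the five-compartment reduced model.

    The force of infection is ``[(1-rho) I_1 + I_inf] * beta / N``; level-0
    infected do not transmit, trusting susceptibles at level 1 acquire with
    the extra factor ``1 - rho``, and infected individuals shuttle between
    levels 0 and 1 through refresh (``omega``) and fading (``lam``).
    """
    y = state.to_array() if isinstance(state, FastLimitState) else np.asarray(state, float)
    if np.any(y < 0):
        raise ValueError("fast-limit state contains negative entries")
    S1, S_inf, I0, I1, I_inf = y
    b, s, w, lam, rho, N = (
        params.beta,
        params.sigma,
        params.omega,
        params.lam,
        params.rho,
        params.N,
    )
    x = 1.0 - rho
    force = (x * I1 + I_inf) * b / N
    return np.array(
        [
            -S1 * x * force,
            -S_inf * force,
            -s * I0 + w * I1 - lam * I0,
            -s * I1 - w * I1 + lam * I0 + S1 * x * force,
            -s * I_inf + S_inf * force,
        ]
    )


def integrate_fast_limit(
    params: ModelParams,
    init: FastLimitState,
    t_max: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
):
    """Integrate the reduced model; returns the scipy solution object."""
    sol = solve_ivp(
        lambda t, y: fast_limit_rhs(np.clip(y, 0.0, None), params),
        (0.0, t_max),
        init.to_array(),
        method="LSODA",
        dense_output=True,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"fast-limit integration failed: {sol.message}")
    return sol


def critical_density(params: ModelParams) -> float:
    """Critical distrusting density ``d_M = sigma / beta = 1 / R_0``.

    Above ``d_M`` suppression is impossible at any ``rho < 1``.  May exceed
    1 (``R_0 < 1``): suppression is then achievable at every composition.
    Returns ``inf`` when ``beta = 0`` (no transmission at all).
    """
    if params.beta == 0.0:
        return math.inf
    return params.sigma / params.beta


def quasi_steady_ratios(params: ModelParams) -> tuple[float, float]:
    """Metastable ratios ``(I_0/I_1, I_inf/I_1)`` of the reduced model.

    Setting ``dI_0/dt = 0`` gives ``I_0 = omega/(sigma+lam) I_1``; setting
    ``dI_inf/dt = 0`` with ``S_inf/N ~ d`` gives
    ``I_inf = beta d (1-rho)/(sigma - beta d) I_1``.  Only defined below the
    critical density ``d < sigma/beta`` (beyond it the stationary ``I_inf``
    would be negative — not a physical regime).
    """
    d_M = critical_density(params)
    if params.d >= d_M:
        raise ValueError(
            f"quasi-steady ratios undefined: d = {params.d} >= d_M = {d_M:.6g} "
            "(stationary unaware-infected mass would be negative)"
        )
    r0 = params.omega / (params.sigma + params.lam)
    r_inf = (
        params.beta
        * params.d
        * (1.0 - params.rho)
        / (params.sigma - params.beta * params.d)
    )
    return r0, r_inf


def critical_quadratic_coeffs(
    d: float, params: ModelParams
) -> tuple[float, float, float]:
    """Coefficients ``(a, b, c)`` of the threshold quadratic in ``x = 1 - rho``.

    ``a x**2 + b x + c = 0`` with ``a = (1-d)(1+dy)``,
    ``b = d (1 + dy - y/R_0)``, ``c = -(1/R_0)(1 + omega/(sigma+lam))``
    where ``y = beta/(sigma - beta d)`` and ``R_0 = beta/sigma``.  ``a > 0``
    and ``c < 0``, so the quadratic always has exactly one positive root.
    """
    if params.beta <= 0.0:
        raise ValueError("critical quadratic requires beta > 0")
    d_M = critical_density(params)
    if not 0.0 <= d < d_M:
        raise ValueError(f"need 0 <= d < d_M = {d_M:.6g}, got d = {d}")
    y = params.beta / (params.sigma - params.beta * d)
    R0 = params.R0
    a = (1.0 - d) * (1.0 + d * y)
    b = d * (1.0 + d * y - y / R0)
    c = -(1.0 / R0) * (1.0 + params.omega / (params.sigma + params.lam))
    return a, b, c


@dataclass
class CriticalRho:
    """Critical intervention effectiveness at one distrusting density.

    ``achievable`` is false at or above the critical density ``d_M`` (then
    ``rho_c`` is ``nan``); ``always_suppressed`` flags compositions where
    even ``rho = 0`` suppresses (the raw root gives ``rho_c <= 0``, reported
    clamped to 0).
    """

    rho_c: float
    achievable: bool
    always_suppressed: bool = False


def critical_rho_analytic(d: float, params: ModelParams) -> CriticalRho:
    """Analytic threshold ``rho_c(d) = 1 - x_+(d)`` from the fast limit.

    ``x_+`` is the positive root of the threshold quadratic.  For
    ``d >= d_M`` the threshold does not exist (suppression unachievable).
    """
    if params.beta == 0.0:
        # no transmission: any rho suppresses
        return CriticalRho(rho_c=0.0, achievable=True, always_suppressed=True)
    d_M = critical_density(params)
    if d >= d_M:
        return CriticalRho(rho_c=math.nan, achievable=False)
    a, b, c = critical_quadratic_coeffs(d, params)
    x_plus = (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    rho_c = 1.0 - x_plus
    if rho_c <= 0.0:
        return CriticalRho(rho_c=0.0, achievable=True, always_suppressed=True)
    return CriticalRho(rho_c=rho_c, achievable=True)


@dataclass
class CriticalCurve:
    """Analytic threshold ``rho_c`` sampled on a grid of densities ``d``.

    ``rho_c`` is ``nan`` where the threshold does not exist
    (``d >= d_M``); ``x`` and ``y`` are the auxiliaries ``1 - rho_c`` and
    ``beta/(sigma - beta d)`` kept for diagnostics.
    """

    d: np.ndarray
    rho_c: np.ndarray
    achievable: np.ndarray
    always_suppressed: np.ndarray
    d_M: float
    x: np.ndarray
    y: np.ndarray
    params: ModelParams

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d,
                "rho_c": self.rho_c,
                "achievable": self.achievable,
                "always_suppressed": self.always_suppressed,
                "x": self.x,
                "y": self.y,
            }
        )


def critical_curve(params: ModelParams, d_grid) -> CriticalCurve:
    """Evaluate the analytic critical curve on a grid of densities."""
    d_grid = np.asarray(d_grid, dtype=float)
    n = d_grid.size
    rho_c = np.full(n, math.nan)
    ach = np.zeros(n, dtype=bool)
    always = np.zeros(n, dtype=bool)
    y = np.full(n, math.nan)
    d_M = critical_density(params)
    for i, d in enumerate(d_grid):
        res = critical_rho_analytic(float(d), params)
        ach[i] = res.achievable
        always[i] = res.always_suppressed
        if res.achievable:
            rho_c[i] = res.rho_c
        if params.beta > 0 and d < d_M:
            y[i] = params.beta / (params.sigma - params.beta * d)
    return CriticalCurve(
        d=d_grid,
        rho_c=rho_c,
        achievable=ach,
        always_suppressed=always,
        d_M=d_M,
        x=1.0 - rho_c,
        y=y,
        params=params,
    )
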