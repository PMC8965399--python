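"""Right-hand sides of the coupled awareness-epidemic ODE system.

Information exchange is contact based.  A trusting individual at level ``j``
who meets anyone holding strictly better information ``i < j`` adopts it at
quality ``i + 1`` (one level is lost in transmission).  A distrusting
individual at level ``j`` conversely adopts information from worse-informed
contacts ``i > j``, again landing at ``i + 1``.  Awareness also fades
spontaneously by one level at rate ``lam``.  Disease dynamics are SIR with
the transmission rate between an infected individual at level ``i`` and a
susceptible at level ``k`` reduced by ``(1 - rho**i) * (1 - rho**k)``;
infected individuals refresh their awareness to level 0 at rate ``omega``.

Finite levels run ``0 .. K-1``; the last index is the unaware infinity
reservoir.  Truncation semantics: a trusting receiver lands at
``min(i + 1, K - 1)`` (stays in the aware chain); a distrusting receiver
accepting from level ``K - 1`` or from the reservoir falls into the
reservoir; fading out of level ``K - 1`` enters the reservoir.  All
exchange and fading terms are pure transfers, so each RHS conserves the
total population exactly.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .params import ModelParams
from .state import PopulationState

__all__ = [
    "protection_factor",
    "protection_profile",
    "info_rhs",
    "full_rhs",
    "effective_beta",
    "effective_R",
]

logger = logging.getLogger(__name__)

_S, _I, _R = 0, 1, 2
_T, _D = 0, 1


def protection_factor(level, rho: float) -> float:
    """Transmission factor ``1 - rho**level`` of awareness level ``level``.

    The infinity reservoir (``level = math.inf`` or ``'inf'``) contributes
    the unaware factor 1.  Level 0 (first-hand information) contributes 0:
    fully aware individuals neither transmit nor acquire the disease.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if level in ("inf",) or level == math.inf:
        return 1.0
    level = int(level)
    if level < 0:
        raise ValueError(f"awareness level must be >= 0, got {level}")
    return 1.0 - rho**level


def protection_profile(K: int, rho: float) -> np.ndarray:
    """Vector of ``1 - rho**i`` for levels ``0..K-1`` plus 1 for the reservoir."""
    p = np.empty(K + 1)
    p[:K] = 1.0 - rho ** np.arange(K)
    p[K] = 1.0
    return p


def _comp(state) -> np.ndarray:
    return state.comp if isinstance(state, PopulationState) else np.asarray(state, float)


def _info_deriv(comp: np.ndarray, params: ModelParams) -> np.ndarray:
    """Awareness-exchange and fading terms, applied to S, I, R alike."""
    K = comp.shape[2] - 1
    aT = params.alpha_T / params.N
    aD = params.alpha_D / params.N
    lam = params.lam

    n = comp.sum(axis=(0, 1))          # total population per level, len K+1
    n_fin = n[:K]
    n_inf = n[K]

    T = comp[:, _T, :]                 # (3, K+1)
    D = comp[:, _D, :]
    dT = np.zeros_like(T)
    dD = np.zeros_like(D)

    # ---- trusting exchange: receiver j adopts from source i <= j - 2 ----
    if aT > 0.0:
        cum_n = np.cumsum(n_fin)       # cum_n[m] = sum_{i<=m} n_i
        # losses: finite receivers j >= 2, and the reservoir (any finite source)
        dT[:, 2:K] -= aT * T[:, 2:K] * cum_n[: K - 2]
        dT[:, K] -= aT * T[:, K] * cum_n[K - 1]
        # gains at level i+1 from source level i: receivers are the trusting
        # mass at levels >= i+2 plus the reservoir
        recv = np.empty((3, K))        # recv[:, i] = sum_{j>=i+2} T_j + T_inf
        suff = np.cumsum(T[:, :K][:, ::-1], axis=1)[:, ::-1]  # suff[:, m] = sum_{j>=m finite}
        recv[:, : K - 2] = suff[:, 2:]
        if K >= 2:
            recv[:, K - 2 :] = 0.0
        recv += T[:, K:]               # reservoir always receives
        dT[:, 1:K] += aT * n_fin[: K - 1] * recv[:, : K - 1]
        # cap: a reservoir individual meeting a level K-1 source lands at K-1
        dT[:, K - 1] += aT * n_fin[K - 1] * T[:, K]

    # ---- distrusting exchange: receiver j adopts from source i >= j + 1 --
    if aD > 0.0:
        suff_n = np.concatenate([np.cumsum(n_fin[::-1])[::-1], [0.0]])  # suff_n[m] = sum_{i>=m} n_i
        dD[:, :K] -= aD * D[:, :K] * (suff_n[1 : K + 1] + n_inf)
        pre = np.cumsum(D[:, :K], axis=1)  # pre[:, m] = sum_{j<=m} D_j
        # gains at level i+1 from finite source i in 1..K-2
        if K >= 3:
            dD[:, 2:K] += aD * n_fin[1 : K - 1] * pre[:, : K - 2]
        # source K-1 or the reservoir send the receiver to the reservoir
        dD[:, K] += aD * (n_fin[K - 1] * pre[:, K - 2] + n_inf * pre[:, K - 1])

    deriv = np.empty_like(comp)
    deriv[:, _T, :] = dT
    deriv[:, _D, :] = dD

    # ---- fading: level k -> k+1, level K-1 -> reservoir ----
    if lam > 0.0:
        deriv[:, :, :K] -= lam * comp[:, :, :K]
        deriv[:, :, 1:] += lam * comp[:, :, :K]
    return deriv


def info_rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivatives of the pure information dynamics.

    Applies the awareness-exchange and fading terms to every disease state
    independently; disease coupling (infection, recovery, refresh) is
    ignored.  The entries sum to zero.
    """
    comp = _comp(state)
    if isinstance(state, PopulationState):
        state.check_shape(params)
    return _info_deriv(comp, params)


def full_rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivatives of the full coupled disease-awareness system."""
    comp = _comp(state)
    if isinstance(state, PopulationState):
        state.check_shape(params)
    K = comp.shape[2] - 1
    deriv = _info_deriv(comp, params)

    p = protection_profile(K, params.rho)
    I_lv = comp[_I].sum(axis=0)                      # infected per level, both groups
    force = params.beta / params.N * float(p @ I_lv)  # awareness-weighted force of infection
    new_inf = comp[_S] * p[None, :] * force          # (2, K+1)
    deriv[_S] -= new_inf
    deriv[_I] += new_inf

    # awareness refresh of infected individuals (levels >= 1 and the reservoir)
    if params.omega > 0.0:
        refreshed = params.omega * comp[_I, :, 1:]
        deriv[_I, :, 1:] -= refreshed
        deriv[_I, :, 0] += refreshed.sum(axis=1)

    recov = params.sigma * comp[_I]
    deriv[_I] -= recov
    deriv[_R] += recov
    return deriv


def effective_beta(state, params: ModelParams) -> float:
    """Awareness-weighted effective transmission rate ``beta_tilde``.

    ``beta_tilde = beta * sum_{i,j} (1-rho**i)(1-rho**j) (I_i/I)(S_j/S)``,
    with the reservoir contributing factor 1.  Always in ``[0, beta]``.
    With no infected or no susceptible mass the weights are undefined; the
    fresh-population limit ``beta`` is returned by convention.
    """
    comp = _comp(state)
    if np.any(comp < 0):
        raise ValueError("state contains negative entries")
    K = comp.shape[2] - 1
    I_lv = comp[_I].sum(axis=0)
    S_lv = comp[_S].sum(axis=0)
    I_tot = I_lv.sum()
    S_tot = S_lv.sum()
    if I_tot == 0.0 or S_tot == 0.0:
        logger.info(
            "effective_beta: I or S is zero; returning baseline beta by convention"
        )
        return params.beta
    p = protection_profile(K, params.rho)
    return params.beta * float(p @ I_lv) / I_tot * float(p @ S_lv) / S_tot


def effective_R(state, params: ModelParams) -> float:
    """Effective reproduction number ``R_e = beta_tilde / sigma``."""
    return effective_beta(state, params) / params.sigma
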