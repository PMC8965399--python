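"""Time integration of the coupled model and epidemic summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import effective_beta, full_rhs
from .params import ModelParams
from .state import PopulationState

__all__ = [
    "make_initial_state",
    "integrate",
    "summarize",
    "Trajectory",
    "EpidemicSummary",
    "DEFAULT_SEED_DENSITY",
    "DEFAULT_END_THRESHOLD",
]

#: initial infected density seeded into each group's unaware reservoir
DEFAULT_SEED_DENSITY = 5e-6
#: epidemic-over threshold: the outbreak has ended once I(t) < threshold * N
DEFAULT_END_THRESHOLD = 1e-7
_S, _I, _R = 0, 1, 2
_T, _D = 0, 1


def make_initial_state(
    params: ModelParams, seed_density: float = DEFAULT_SEED_DENSITY
) -> PopulationState:
    """Almost fully susceptible, fully unaware population with a small seed.

    A density ``seed_density`` of infected individuals is placed in the
    unaware reservoir of *each* group; the rest of the population is
    susceptible and unaware, split ``1 - d`` trusting / ``d`` distrusting.
    """
    if not 0.0 < seed_density < 1.0:
        raise ValueError(f"seed_density must be in (0, 1), got {seed_density}")
    if params.d < seed_density:
        raise ValueError(
            f"cannot seed infected density {seed_density} in the distrusting "
            f"group: its share is only d = {params.d}"
        )
    if 1.0 - params.d < seed_density:
        raise ValueError(
            f"cannot seed infected density {seed_density} in the trusting "
            f"group: its share is only 1 - d = {1.0 - params.d}"
        )
    state = PopulationState.zeros(params.K)
    N = params.N
    state.comp[_I, _T, params.K] = seed_density * N
    state.comp[_I, _D, params.K] = seed_density * N
    state.comp[_S, _T, params.K] = (1.0 - params.d - seed_density) * N
    state.comp[_S, _D, params.K] = (params.d - seed_density) * N
    return state


@dataclass
class Trajectory:
    """Numerical solution of the coupled system on ``[0, t_end]``.

    ``comps`` stores the full compartment array at each output time;
    ``S``, ``I``, ``R`` are disease-state totals, ``beta_eff`` and ``R_e``
    the awareness-weighted effective transmission rate and reproduction
    number along the solution.
    """

    times: np.ndarray
    comps: np.ndarray  # (n_times, 3, 2, K+1)
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    beta_eff: np.ndarray
    R_e: np.ndarray
    params: ModelParams
    end_threshold: float
    ended: bool  # True if I(t) fell below end_threshold * N within the horizon
    segments: list = field(default_factory=list, repr=False)  # dense OdeSolution pieces

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def state_at(self, t: float) -> PopulationState:
        """Dense-output state at an arbitrary time inside the horizon."""
        for seg in self.segments:
            if seg.t_min <= t <= seg.t_max:
                y = seg(t)
                K = self.comps.shape[3] - 1
                return PopulationState(y.reshape(3, 2, K + 1))
        raise ValueError(f"t={t} outside the integrated interval [0, {self.t_end}]")

    def I_at(self, t: float) -> float:
        return float(self.state_at(t).comp[_I].sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy aggregate time series (time, S, I, R, beta_eff, R_e)."""
        return pd.DataFrame(
            {
                "time": self.times,
                "S": self.S,
                "I": self.I,
                "R": self.R,
                "beta_eff": self.beta_eff,
                "R_e": self.R_e,
            }
        )

    def compartments_to_dataframe(self) -> pd.DataFrame:
        """Wide per-compartment time series, columns like ``S_T_0 .. R_D_inf``."""
        from .state import DISEASE_STATES, GROUPS

        K = self.comps.shape[3] - 1
        data = {"time": self.times}
        for a, dis in enumerate(DISEASE_STATES):
            for b, grp in enumerate(GROUPS):
                for lv in range(K + 1):
                    name = f"{dis}_{grp}_{lv if lv < K else 'inf'}"
                    data[name] = self.comps[:, a, b, lv]
        return pd.DataFrame(data)


@dataclass
class EpidemicSummary:
    """Headline outbreak metrics extracted from a trajectory.

    ``converged`` means the outbreak is over (I below the end threshold);
    ``peak_covered`` means the infection maximum lies inside the horizon
    (I is declining at the end), which can hold long before convergence —
    the tail of a suppressed or near-boundary epidemic decays very slowly.
    """

    peak_I: float
    t_peak: float
    final_S: float
    duration: float
    total_infected: float
    converged: bool
    peak_covered: bool = True

    def to_dict(self) -> dict:
        return {
            "peak_I": self.peak_I,
            "t_peak": self.t_peak,
            "final_S": self.final_S,
            "duration": self.duration,
            "total_infected": self.total_infected,
            "converged": self.converged,
            "peak_covered": self.peak_covered,
        }


def integrate(
    params: ModelParams,
    init: PopulationState | None = None,
    t_max: float = 1000.0,
    *,
    seed_density: float = DEFAULT_SEED_DENSITY,
    end_threshold: float = DEFAULT_END_THRESHOLD,
    extend: bool = True,
    max_t: float = 16000.0,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float | None = None,
    n_points: int = 2001,
) -> Trajectory:
    """Integrate the full coupled system.

    The solve runs as a single adaptive pass: up to ``t_max`` when
    ``extend`` is false, and up to ``max_t`` otherwise — near the
    suppression/mitigation boundary the infection level plateaus and
    epidemics become very long.  A terminal event stops the integration
    early once the outbreak is over (total infected below
    ``end_threshold * N``), so generous horizons cost little.  The stored
    time series samples the dense solver output on ``n_points`` uniform
    times over the realised interval.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    if init is None:
        init = make_initial_state(params, seed_density)
    init.check_shape(params)
    K = params.K
    N = params.N
    if atol is None:
        atol = 1e-12 * N
    thr = end_threshold * N

    def rhs(t, y):
        return full_rhs(y.reshape(3, 2, K + 1), params).ravel()

    def outbreak_over(t, y):
        return y.reshape(3, 2, K + 1)[_I].sum() - thr

    outbreak_over.terminal = True
    outbreak_over.direction = -1

    horizon = max(float(t_max), float(max_t)) if extend else float(t_max)
    y0 = init.comp.ravel().copy()
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method=method,
        dense_output=True,
        events=[outbreak_over],
        rtol=rtol,
        atol=atol,
    )
    if not sol.success and sol.status != 1:
        t_last = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"ODE solver failed at t = {t_last}: {sol.message}")
    segments = [sol.sol]
    t_end = float(sol.t_events[0][0]) if sol.status == 1 else float(sol.t[-1])
    ended = sol.status == 1 or sol.y[:, -1].reshape(3, 2, K + 1)[_I].sum() <= thr

    times = np.linspace(0.0, t_end, n_points)
    comps = sol.sol(times).T.reshape(-1, 3, 2, K + 1)
    comps[0] = init.comp  # dense output is exact at the ends; keep them exact
    comps[-1] = (sol.y_events[0][0] if sol.status == 1 else sol.y[:, -1]).reshape(
        3, 2, K + 1
    )
    S = comps[:, _S].sum(axis=(1, 2))
    I = comps[:, _I].sum(axis=(1, 2))
    R = comps[:, _R].sum(axis=(1, 2))
    beta_eff = np.array(
        [effective_beta(np.clip(c, 0.0, None), params) for c in comps]
    )
    return Trajectory(
        times=times,
        comps=comps,
        S=S,
        I=I,
        R=R,
        beta_eff=beta_eff,
        R_e=beta_eff / params.sigma,
        params=params,
        end_threshold=end_threshold,
        ended=ended,
        segments=segments,
    )


def _refine_peak(traj: Trajectory, idx: int) -> tuple[float, float]:
    """Quadratic refinement of the discrete argmax of I(t).

    Fits a parabola through the argmax sample and its neighbours and
    re-evaluates I at the fitted vertex on the dense solver output; falls
    back to the discrete sample at the interval ends or for degenerate fits.
    """
    t, I = traj.times, traj.I
    if idx == 0 or idx == len(t) - 1:
        return float(t[idx]), float(I[idx])
    t3 = t[idx - 1 : idx + 2]
    I3 = I[idx - 1 : idx + 2]
    denom = (t3[0] - t3[1]) * (t3[0] - t3[2]) * (t3[1] - t3[2])
    if denom == 0.0:
        return float(t[idx]), float(I[idx])
    a = (
        t3[2] * (I3[1] - I3[0]) + t3[1] * (I3[0] - I3[2]) + t3[0] * (I3[2] - I3[1])
    ) / denom
    if a >= 0.0:
        return float(t[idx]), float(I[idx])
    b = (
        t3[2] ** 2 * (I3[0] - I3[1])
        + t3[1] ** 2 * (I3[2] - I3[0])
        + t3[0] ** 2 * (I3[1] - I3[2])
    ) / denom
    t_star = -b / (2.0 * a)
    if not t3[0] <= t_star <= t3[2]:
        return float(t[idx]), float(I[idx])
    try:
        I_star = traj.I_at(t_star)
    except ValueError:
        return float(t[idx]), float(I[idx])
    if I_star < I[idx]:
        return float(t[idx]), float(I[idx])
    return float(t_star), float(I_star)


def summarize(traj: Trajectory, end_threshold: float | None = None) -> EpidemicSummary:
    """Peak size and timing, final susceptibles, and epidemic duration.

    ``duration`` is the first time after the peak at which the total
    infected falls below ``end_threshold * N`` (the integration horizon if
    it never does).
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    if end_threshold is None:
        end_threshold = traj.end_threshold
    N = traj.params.N
    thr = end_threshold * N

    idx = int(np.argmax(traj.I))
    t_peak, peak_I = _refine_peak(traj, idx)
    final_S = float(traj.S[-1])

    below = np.nonzero((traj.times > t_peak) & (traj.I < thr))[0]
    if below.size:
        j = below[0]
        lo = max(j - 1, 0)
        if traj.I[lo] >= thr and traj.times[lo] >= t_peak:
            from scipy.optimize import brentq

            duration = float(
                brentq(
                    lambda t: traj.I_at(t) - thr, traj.times[lo], traj.times[j], xtol=1e-6
                )
            )
        else:
            duration = float(traj.times[j])
    else:
        duration = traj.t_end
    duration = max(duration, t_peak)

    converged = bool(traj.I[-1] < thr)
    still_rising = (
        not converged
        and len(traj.I) >= 2
        and traj.I[-1] > traj.I[-2] * (1.0 + 1e-9)
    )
    if still_rising:
        warnings.warn(
            "trajectory ends while I(t) is still rising; the reported peak "
            "may not be the epidemic peak",
            stacklevel=2,
        )
    return EpidemicSummary(
        peak_I=peak_I,
        t_peak=t_peak,
        final_S=final_S,
        duration=duration,
        total_infected=N - final_S,
        converged=converged,
        peak_covered=not still_rising,
    )
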