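"""Suppression/mitigation classification and numerical phase boundaries.

The coupled model exhibits two regimes.  In the *suppression* regime the
behavioural feedback keeps the outbreak at the seed scale (a very low, early
peak); in the *mitigation* regime a large outbreak proceeds with a reduced,
delayed peak.  The boundary ``rho_c(d)`` separates them: approaching it
from either side the infection level plateaus and the time to the peak
diverges, so the boundary can be located either as the jump of the peak
size through a threshold or as the argmax of the time-to-peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fast_limit import critical_curve as _analytic_curve
from .params import ModelParams
from .simulate import (
    DEFAULT_END_THRESHOLD,
    DEFAULT_SEED_DENSITY,
    EpidemicSummary,
    integrate,
    summarize,
)

__all__ = [
    "classify_regime",
    "critical_rho_numeric",
    "phase_diagram",
    "PhaseGrid",
    "SUPPRESSION",
    "MITIGATION",
    "UNDETERMINED",
    "DEFAULT_PEAK_THRESHOLD",
]

logger = logging.getLogger(__name__)

SUPPRESSION = "suppression"
MITIGATION = "mitigation"
UNDETERMINED = "undetermined"

#: suppression iff peak_I/N below this; ten times the total seed density
DEFAULT_PEAK_THRESHOLD = 10 * 2 * DEFAULT_SEED_DENSITY


def classify_regime(
    summary: EpidemicSummary,
    params: ModelParams,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> str:
    """Label an epidemic summary as suppression or mitigation.

    Suppression requires ``peak_I / N`` strictly below ``peak_threshold``
    (a peak exactly at the threshold counts as mitigation).  A peak above
    the threshold is mitigation regardless of how slowly the tail decays;
    a sub-threshold maximum is suppression only if the peak was actually
    covered — a trajectory still rising at its fully extended horizon is
    labelled undetermined (it sits on the plateau at the boundary).
    """
    if summary.peak_I / params.N >= peak_threshold:
        return MITIGATION
    if not summary.peak_covered:
        return UNDETERMINED
    return SUPPRESSION


def _summary_at(
    params: ModelParams,
    rho: float,
    d: float,
    *,
    seed_density: float,
    end_threshold: float,
    t_max: float,
    max_t: float,
    rtol: float,
    K: int | None = None,
) -> EpidemicSummary:
    p = params.with_(rho=float(rho), d=float(d), K=K)
    traj = integrate(
        p,
        seed_density=seed_density,
        end_threshold=end_threshold,
        t_max=t_max,
        max_t=max_t,
        rtol=rtol,
    )
    return summarize(traj)


def critical_rho_numeric(
    d: float,
    params: ModelParams,
    *,
    bracket: tuple[float, float] = (0.02, 0.98),
    xtol: float = 0.01,
    method: str = "threshold",
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    seed_density: float = DEFAULT_SEED_DENSITY,
    end_threshold: float = DEFAULT_END_THRESHOLD,
    t_max: float = 1000.0,
    max_t: float = 16000.0,
    rtol: float = 1e-8,
    coarse_points: int = 9,
    K: int | None = None,
) -> float:
    """Locate the suppression/mitigation boundary in ``rho`` at fixed ``d``.

    Two detectors are available.  ``"threshold"`` (default) bisects on the
    peak-size classifier: the boundary is where ``peak_I/N`` crosses
    ``peak_threshold``.  ``"tpeak"`` maximises the time to the infection
    peak over ``rho`` (coarse grid plus golden-section refinement) — the
    boundary plateau makes epidemics longest exactly at the transition.
    Returns ``nan`` ("unachievable") when the whole bracket lies in the
    mitigation regime (``d`` above the critical density).

    ``K`` overrides the per-``rho`` default truncation depth for every
    simulation in the search.  In the fast-information regime the awareness
    distribution concentrates on levels {0, 1, reservoir}, so a fixed
    moderate depth is exact there and avoids the very deep truncations the
    default rule picks at large ``rho``; verify with a doubling check.
    """
    lo, hi = bracket
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"bracket must satisfy 0 < lo < hi < 1, got {bracket}")
    kw = dict(
        seed_density=seed_density,
        end_threshold=end_threshold,
        t_max=t_max,
        max_t=max_t,
        rtol=rtol,
        K=K,
    )

    if method == "threshold":

        def is_supp(rho: float) -> bool:
            s = _summary_at(params, rho, d, **kw)
            label = classify_regime(s, params, peak_threshold)
            # an undetermined cell sits on the boundary plateau with a
            # sub-threshold maximum: count it with the suppression side
            return label != MITIGATION

        if is_supp(lo):
            return lo  # boundary below the bracket: suppression everywhere
        if not is_supp(hi):
            return math.nan  # mitigation everywhere: unachievable in-bracket
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if is_supp(mid):
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    if method == "tpeak":

        def t_peak(rho: float) -> float:
            return _summary_at(params, rho, d, **kw).t_peak

        grid = np.linspace(lo, hi, coarse_points)
        vals = [t_peak(r) for r in grid]
        k = int(np.argmax(vals))
        if k == len(grid) - 1:
            return math.nan  # t_peak still rising at the top of the bracket
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        c = b - invphi * (b - a)
        e = a + invphi * (b - a)
        fc, fe = t_peak(c), t_peak(e)
        while b - a > xtol:
            if fc > fe:
                b, e, fe = e, c, fc
                c = b - invphi * (b - a)
                fc = t_peak(c)
            else:
                a, c, fc = c, e, fe
                e = a + invphi * (b - a)
                fe = t_peak(e)
        return 0.5 * (a + b)

    raise ValueError(f"unknown method {method!r}; use 'threshold' or 'tpeak'")


@dataclass
class PhaseGrid:
    """Outbreak summaries and regime labels on a (d, rho) grid.

    Arrays are indexed ``[i_d, i_rho]``.  ``rho_c_numeric`` holds, per
    density column, the midpoint between the last mitigation cell and the
    first suppression cell along increasing ``rho`` (``nan`` if the column
    is single-regime); ``rho_c_analytic`` is the fast-limit prediction on
    the same densities.
    """

    rho: np.ndarray
    d: np.ndarray
    t_peak: np.ndarray
    peak_I: np.ndarray
    final_S: np.ndarray
    regime: np.ndarray  # dtype=object strings
    rho_c_numeric: np.ndarray
    rho_c_analytic: np.ndarray
    params: ModelParams
    errors: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per (rho, d) cell."""
        dd, rr = np.meshgrid(self.d, self.rho, indexing="ij")
        return pd.DataFrame(
            {
                "rho": rr.ravel(),
                "d": dd.ravel(),
                "t_peak": self.t_peak.ravel(),
                "peak_I": self.peak_I.ravel(),
                "final_S": self.final_S.ravel(),
                "regime": self.regime.ravel(),
            }
        )

    def boundary_dict(self) -> dict:
        return {
            "d": self.d.tolist(),
            "rho_c_numeric": [
                None if math.isnan(v) else v for v in self.rho_c_numeric
            ],
            "rho_c_analytic": [
                None if math.isnan(v) else v for v in self.rho_c_analytic
            ],
        }


def phase_diagram(
    params: ModelParams,
    rho_grid,
    d_grid,
    *,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    seed_density: float = DEFAULT_SEED_DENSITY,
    end_threshold: float = DEFAULT_END_THRESHOLD,
    t_max: float = 1000.0,
    max_t: float = 16000.0,
    rtol: float = 1e-8,
    K: int | None = None,
) -> PhaseGrid:
    """Simulate and classify every cell of a (rho, d) grid.

    Per-cell failures are recorded in ``PhaseGrid.errors`` (with nan
    entries) rather than aborting the scan.  Fully deterministic given the
    parameters and grids.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if rho_grid.size == 0 or d_grid.size == 0:
        raise ValueError("rho and d grids must be non-empty")
    if np.any((rho_grid <= 0) | (rho_grid >= 1)):
        raise ValueError("rho grid must lie inside (0, 1)")
    if np.any((d_grid < 0) | (d_grid >= 1)):
        raise ValueError("d grid must lie inside [0, 1)")

    shape = (d_grid.size, rho_grid.size)
    t_peak = np.full(shape, math.nan)
    peak_I = np.full(shape, math.nan)
    final_S = np.full(shape, math.nan)
    regime = np.full(shape, UNDETERMINED, dtype=object)
    errors: list[tuple[float, float, str]] = []

    for i, d in enumerate(d_grid):
        for j, rho in enumerate(rho_grid):
            try:
                s = _summary_at(
                    params,
                    rho,
                    d,
                    seed_density=seed_density,
                    end_threshold=end_threshold,
                    t_max=t_max,
                    max_t=max_t,
                    rtol=rtol,
                    K=K,
                )
            except Exception as exc:  # recorded, not fatal
                errors.append((float(rho), float(d), str(exc)))
                logger.warning("cell (rho=%g, d=%g) failed: %s", rho, d, exc)
                continue
            t_peak[i, j] = s.t_peak
            peak_I[i, j] = s.peak_I
            final_S[i, j] = s.final_S
            regime[i, j] = classify_regime(s, params, peak_threshold)
            logger.debug(
                "cell (rho=%g, d=%g): %s, peak_I=%g, t_peak=%g",
                rho,
                d,
                regime[i, j],
                s.peak_I,
                s.t_peak,
            )

    # per-column boundary: midpoint between the last mitigation and the
    # first suppression cell along increasing rho
    rho_c_num = np.full(d_grid.size, math.nan)
    for i in range(d_grid.size):
        labels = regime[i]
        supp = np.array([lab == SUPPRESSION for lab in labels])
        mit = np.array([lab == MITIGATION for lab in labels])
        if supp.any() and mit.any():
            j_first_supp = int(np.argmax(supp))
            j_last_mit = int(np.where(mit)[0][-1])
            if j_last_mit < j_first_supp:
                rho_c_num[i] = 0.5 * (rho_grid[j_last_mit] + rho_grid[j_first_supp])
            else:  # non-monotone labelling: use the first transition
                trans = np.nonzero(mit[:-1] & supp[1:])[0]
                if trans.size:
                    rho_c_num[i] = 0.5 * (
                        rho_grid[trans[0]] + rho_grid[trans[0] + 1]
                    )

    analytic = _analytic_curve(params, d_grid).rho_c
    return PhaseGrid(
        rho=rho_grid,
        d=d_grid,
        t_peak=t_peak,
        peak_I=peak_I,
        final_S=final_S,
        regime=regime,
        rho_c_numeric=rho_c_num,
        rho_c_analytic=analytic,
        params=params,
        errors=errors,
    )


def plot_phase_grid(grid: PhaseGrid, ax=None, value: str = "t_peak"):
    """Heat-map of a phase grid (time-to-peak by default) with boundaries."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    data = getattr(grid, value)
    mesh = ax.pcolormesh(grid.d, grid.rho, data.T, shading="nearest")
    ok = ~np.isnan(grid.rho_c_analytic)
    if ok.any():
        ax.plot(grid.d[ok], grid.rho_c_analytic[ok], "k--", label="analytic rho_c(d)")
    ok = ~np.isnan(grid.rho_c_numeric)
    if ok.any():
        ax.plot(grid.d[ok], grid.rho_c_numeric[ok], "w.", label="numeric rho_c(d)")
    ax.set_xlabel("distrusting density d")
    ax.set_ylabel("intervention effectiveness rho")
    ax.legend(loc="best")
    plt.colorbar(mesh, ax=ax, label=value)
    return ax
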