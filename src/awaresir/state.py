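"""Population state container.

The state is a non-negative array ``comp[disease, group, level]`` with
``disease in {S, I, R}``, ``group in {T (trusting), D (distrusting)}`` and
``level in {0, .., K-1, inf}``; the last level index is the fully unaware
infinity reservoir.  The dynamics conserve ``comp.sum() == N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = ["PopulationState", "Aggregates", "DISEASE_STATES", "GROUPS"]

DISEASE_STATES = ("S", "I", "R")
GROUPS = ("T", "D")
_S, _I, _R = 0, 1, 2
_T, _D = 0, 1


@dataclass
class Aggregates:
    """Marginals of a :class:`PopulationState`.

    ``S``, ``I``, ``R`` are disease-state totals; ``t_levels``/``d_levels``
    are the per-level totals of the trusting/distrusting groups (all disease
    states), and ``I_levels``/``S_levels`` the per-level infected and
    susceptible totals (both groups).  Level arrays have length ``K + 1``
    with the unaware reservoir last.
    """

    S: float
    I: float
    R: float
    t_levels: np.ndarray
    d_levels: np.ndarray
    I_levels: np.ndarray
    S_levels: np.ndarray


class PopulationState:
    """Compartment occupancies ``X[Y, i]`` of the coupled model."""

    def __init__(self, comp: np.ndarray):
        comp = np.asarray(comp, dtype=float)
        if comp.ndim != 3 or comp.shape[0] != 3 or comp.shape[1] != 2 or comp.shape[2] < 3:
            raise ValueError(
                f"state must have shape (3, 2, K+1) with K >= 2, got {comp.shape}"
            )
        self.comp = comp

    @classmethod
    def zeros(cls, K: int) -> "PopulationState":
        return cls(np.zeros((3, 2, K + 1)))

    @property
    def K(self) -> int:
        """Number of finite awareness levels."""
        return self.comp.shape[2] - 1

    def copy(self) -> "PopulationState":
        return PopulationState(self.comp.copy())

    def total(self) -> float:
        return float(self.comp.sum())

    def check_shape(self, params: ModelParams) -> None:
        if self.K != params.K:
            raise ValueError(
                f"state has {self.K} finite levels but params.K = {params.K}"
            )

    # -- named accessors -------------------------------------------------
    def get(self, disease: str, group: str, level) -> float:
        """Occupancy of one compartment; ``level`` may be an int or 'inf'."""
        i = self.K if level in ("inf", np.inf) else int(level)
        return float(self.comp[DISEASE_STATES.index(disease), GROUPS.index(group), i])

    def set(self, disease: str, group: str, level, value: float) -> None:
        i = self.K if level in ("inf", np.inf) else int(level)
        self.comp[DISEASE_STATES.index(disease), GROUPS.index(group), i] = value

    def aggregate(self) -> Aggregates:
        """Disease-state totals and per-level marginals."""
        c = self.comp
        return Aggregates(
            S=float(c[_S].sum()),
            I=float(c[_I].sum()),
            R=float(c[_R].sum()),
            t_levels=c[:, _T, :].sum(axis=0),
            d_levels=c[:, _D, :].sum(axis=0),
            I_levels=c[_I].sum(axis=0),
            S_levels=c[_S].sum(axis=0),
        )

    def __repr__(self) -> str:  # pragma: no cover
        a = self.aggregate()
        return (
            f"PopulationState(K={self.K}, N={self.total():.6g}, "
            f"S={a.S:.6g}, I={a.I:.6g}, R={a.R:.6g})"
        )
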