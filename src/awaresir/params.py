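"""Model parameters for the coupled awareness-epidemic system.

The model couples SIR disease dynamics to a contact-based information
(awareness) process in a population split into *trusting* individuals, who
adopt better-quality information from their contacts, and *distrusting*
individuals, who adopt worse-quality information.  Awareness quality is a
non-negative integer level ``i`` (0 = freshest, first-hand information);
an individual at level ``i`` reduces transmission by the protection factor
``1 - rho**i``.  Fully unaware individuals live in an explicit infinity
reservoir.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["ModelParams", "default_truncation"]

#: occupancy below this protection difference is folded into the unaware
#: reservoir when choosing the default truncation depth
_TRUNCATION_TOL = 1e-6


def default_truncation(rho: float, tol: float = _TRUNCATION_TOL) -> int:
    """Number of finite awareness levels ``K`` such that ``rho**(K-1) < tol``.

    At level ``K - 1`` the protection factor ``1 - rho**(K-1)`` is then
    indistinguishable from the unaware value 1, so deeper levels carry no
    behavioural information and are merged into the infinity reservoir.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return 2
    return max(2, math.ceil(math.log(tol) / math.log(rho)) + 1)


@dataclass(frozen=True)
class ModelParams:
    """Rates and population composition of the coupled model.

    Parameters
    ----------
    beta : float
        Baseline transmission rate (per day) with no protective measures.
    sigma : float
        Recovery rate (per day).
    rho : float
        Effectiveness of non-pharmaceutical interventions, in ``[0, 1)``.
        An individual at awareness level ``i`` transmits/acquires with the
        factor ``1 - rho**i``.
    alpha_T, alpha_D : float
        Information-encounter rates (per day) of the trusting and
        distrusting sub-populations.
    lam : float
        Awareness fading rate (per day); fading degrades quality by one
        level.
    omega : float
        Rate (per day) at which infected individuals realise their
        condition and refresh their awareness to level 0.
    d : float
        Initial density of distrusting individuals, in ``[0, 1]``.
    N : float
        Total population size.  The dynamics are homogeneous of degree one
        in the compartments, so running at ``N = 1`` (densities) gives
        identical results up to scale.
    K : int, optional
        Number of finite awareness levels ``0 .. K-1`` retained; levels
        beyond ``K-1`` are merged into the unaware reservoir.  Defaults to
        the smallest depth at which ``rho**(K-1) < 1e-6``.
    """

    beta: float
    sigma: float
    rho: float
    alpha_T: float
    alpha_D: float
    lam: float
    omega: float
    d: float
    N: float = 1.0
    K: int | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        for name in ("alpha_T", "alpha_D", "lam", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"d must be in [0, 1], got {self.d}")
        if self.N <= 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if self.K is None:
            object.__setattr__(self, "K", default_truncation(self.rho))
        elif int(self.K) < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        else:
            object.__setattr__(self, "K", int(self.K))

    @property
    def R0(self) -> float:
        """Basic reproduction number ``beta / sigma``."""
        return self.beta / self.sigma

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with fields replaced.

        ``K`` is recomputed from the (possibly new) ``rho`` unless given
        explicitly.
        """
        if "K" not in kwargs:
            kwargs["K"] = None
        return replace(self, **kwargs)
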