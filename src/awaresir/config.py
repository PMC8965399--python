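"""Run configuration: validated parameter files for the command line."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import ModelParams

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """Declarative description of one run (simulation, phase scan or curve).

    Flat key/value YAML; unknown keys are rejected.  CLI flags override
    file values.
    """

    model_config = ConfigDict(extra="forbid")

    # model parameters
    beta: float = 0.667
    sigma: float = 0.133
    rho: float = Field(default=0.8, ge=0.0, lt=1.0)
    alpha_T: float = 5.0
    alpha_D: float = 5.0
    lam: float = 0.2
    omega: float = 0.333
    d: float = Field(default=0.1, ge=0.0, le=1.0)
    N: float = 1.0
    K: Optional[int] = None

    # simulation options
    seed_density: float = 5e-6
    t_max: float = 1000.0
    max_t: float = 16000.0
    end_threshold: float = 1e-7
    rtol: float = 1e-8
    atol: Optional[float] = None
    method: str = "LSODA"

    # phase/curve grids
    rho_grid: Optional[list[float]] = None
    d_grid: Optional[list[float]] = None
    peak_threshold: float = 1e-4
    boundary_xtol: float = 0.01

    # output
    out_dir: str = "."
    wide_csv: bool = False  # also write the per-compartment trajectory
    plot: bool = False

    @model_validator(mode="after")
    def _check_rates(self) -> "RunConfig":
        for name in ("beta", "alpha_T", "alpha_D", "lam", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.N <= 0:
            raise ValueError("N must be > 0")
        if not 0.0 < self.seed_density < 1.0:
            raise ValueError("seed_density must be in (0, 1)")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def model_params(self) -> ModelParams:
        return ModelParams(
            beta=self.beta,
            sigma=self.sigma,
            rho=self.rho,
            alpha_T=self.alpha_T,
            alpha_D=self.alpha_D,
            lam=self.lam,
            omega=self.omega,
            d=self.d,
            N=self.N,
            K=self.K,
        )
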