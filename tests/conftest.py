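import numpy as np
import pytest

from awaresir import ModelParams


@pytest.fixture
def baseline_params() -> ModelParams:
    """Headline trajectory parameter set (R_0 ~ 5, moderate info spread)."""
    return ModelParams(
        beta=0.667,
        sigma=0.133,
        rho=0.8,
        alpha_T=5.0,
        alpha_D=5.0,
        lam=0.2,
        omega=0.333,
        d=0.1,
    )


@pytest.fixture
def fast_info_params() -> ModelParams:
    """Fast-information regime used for the analytic threshold."""
    return ModelParams(
        beta=0.333,
        sigma=0.133,
        rho=0.5,
        alpha_T=1e6,
        alpha_D=1e6,
        lam=0.2,
        omega=0.33,
        d=0.2,
    )


def random_state(rng: np.random.Generator, K: int, N: float = 1.0) -> np.ndarray:
    """Random non-negative compartment array normalised to total N."""
    c = rng.random((3, 2, K + 1))
    return c * (N / c.sum())
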