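"""Core right-hand-side tests: protection factors, information dynamics,
the full coupled field, and the effective transmission rate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import poisson

from awaresir import (
    ModelParams,
    PopulationState,
    effective_beta,
    effective_R,
    full_rhs,
    info_rhs,
    protection_factor,
)
from conftest import random_state


@pytest.mark.parametrize(
    "level,rho,expected",
    [
        (0, 0.8, 0.0),  # fully aware individuals neither transmit nor acquire
        (math.inf, 0.8, 1.0),  # unaware reservoir: no protection
        (1, 0.5, 0.5),
        (2, 0.5, 0.75),
        (0, 0.0, 0.0),
        (3, 0.0, 1.0),
    ],
)
def test_protection_factor(level, rho, expected):
    assert protection_factor(level, rho) == pytest.approx(expected, abs=1e-15)


def test_protection_factor_rejects_bad_arguments():
    with pytest.raises(ValueError):
        protection_factor(-1, 0.5)
    with pytest.raises(ValueError):
        protection_factor(1, 1.0)


class TestInfoDynamics:
    def test_static_when_no_interaction_and_no_fading(self):
        p = ModelParams(beta=0.5, sigma=0.1, rho=0.5, alpha_T=0, alpha_D=0,
                        lam=0, omega=0, d=0.3, K=6)
        state = PopulationState.zeros(6)
        state.set("S", "T", 2, 0.7)
        state.set("S", "D", 2, 0.3)
        assert np.all(info_rhs(state, p) == 0.0)

    def test_fading_chain_matches_poisson_cascade(self):
        """With no exchange, fading from level 0 is a Poisson cascade:
        occupancy of level k at time t is the Poisson pmf exp(-lt)(lt)^k/k!."""
        lam, K, t_end = 0.2, 12, 8.0
        p = ModelParams(beta=0.5, sigma=0.1, rho=0.5, alpha_T=0, alpha_D=0,
                        lam=lam, omega=0, d=0.0, K=K)
        y0 = np.zeros((3, 2, K + 1))
        y0[0, 0, 0] = 1.0  # all trusting susceptibles, fully aware
        sol = solve_ivp(
            lambda t, y: info_rhs(y.reshape(3, 2, K + 1), p).ravel(),
            (0, t_end), y0.ravel(), rtol=1e-10, atol=1e-14,
        )
        occ = sol.y[:, -1].reshape(3, 2, K + 1)[0, 0, :K - 1]
        expected = poisson.pmf(np.arange(K - 1), lam * t_end)
        np.testing.assert_allclose(occ, expected, atol=1e-9)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_on_random_states(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 30))
        p = ModelParams(
            beta=float(rng.uniform(0, 1)), sigma=float(rng.uniform(0.05, 0.5)),
            rho=float(rng.uniform(0, 0.99)), alpha_T=float(rng.uniform(0, 50)),
            alpha_D=float(rng.uniform(0, 50)), lam=float(rng.uniform(0, 1)),
            omega=float(rng.uniform(0, 1)), d=float(rng.uniform(0, 1)), K=K,
        )
        c = random_state(rng, K)
        assert abs(info_rhs(c, p).sum()) < 1e-12 * p.N
        assert abs(full_rhs(c, p).sum()) < 1e-12 * p.N

    def test_shape_mismatch_raises(self):
        p = ModelParams(beta=0.5, sigma=0.1, rho=0.5, alpha_T=1, alpha_D=1,
                        lam=0.1, omega=0.1, d=0.2, K=5)
        with pytest.raises(ValueError):
            info_rhs(PopulationState.zeros(8), p)


class TestFullField:
    def test_reduces_to_classical_sir(self):
        """With omega = 0 and an entirely unaware population the field on
        (S, I, R) totals is exactly the classical SIR right-hand side."""
        p = ModelParams(beta=0.667, sigma=0.133, rho=0.8, alpha_T=5,
                        alpha_D=5, lam=0.2, omega=0.0, d=0.3, K=8)
        state = PopulationState.zeros(8)
        state.set("S", "T", "inf", 0.65)
        state.set("S", "D", "inf", 0.25)
        state.set("I", "T", "inf", 0.04)
        state.set("I", "D", "inf", 0.05)
        state.set("R", "T", "inf", 0.01)
        d = full_rhs(state, p)
        S, I = 0.90, 0.09
        assert d[0].sum() == pytest.approx(-p.beta * S * I, abs=1e-15)
        assert d[1].sum() == pytest.approx(p.beta * S * I - p.sigma * I, abs=1e-15)
        assert d[2].sum() == pytest.approx(p.sigma * I, abs=1e-15)

    def test_fully_aware_infected_cause_no_infections(self):
        p = ModelParams(beta=0.667, sigma=0.133, rho=0.8, alpha_T=0,
                        alpha_D=0, lam=0, omega=0, d=0.3, K=5)
        state = PopulationState.zeros(5)
        state.set("S", "T", 3, 0.5)
        state.set("S", "D", "inf", 0.3)
        state.set("I", "T", 0, 0.2)  # all infected hold first-hand information
        d = full_rhs(state, p)
        assert np.all(d[0] == 0.0)  # no susceptible is ever infected

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_aggregation_identity(self, seed):
        """Summing the full field over awareness levels gives SIR-form
        aggregate dynamics driven by the effective transmission rate."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 20))
        p = ModelParams(
            beta=float(rng.uniform(0.1, 1)), sigma=float(rng.uniform(0.05, 0.5)),
            rho=float(rng.uniform(0, 0.99)), alpha_T=float(rng.uniform(0, 20)),
            alpha_D=float(rng.uniform(0, 20)), lam=float(rng.uniform(0, 1)),
            omega=float(rng.uniform(0, 1)), d=float(rng.uniform(0, 1)), K=K,
        )
        c = random_state(rng, K)
        d = full_rhs(c, p)
        bt = effective_beta(c, p)
        S, I = c[0].sum(), c[1].sum()
        assert d[0].sum() == pytest.approx(-bt * S * I / p.N, abs=1e-10 * p.N)
        assert d[1].sum() == pytest.approx(bt * S * I / p.N - p.sigma * I, abs=1e-10 * p.N)
        assert d[2].sum() == pytest.approx(p.sigma * I, abs=1e-10 * p.N)


class TestEffectiveBeta:
    def _params(self, **kw):
        kw.setdefault("K", 5)
        return ModelParams(beta=kw.pop("beta", 0.667), sigma=0.133,
                           rho=kw.pop("rho", 0.5), alpha_T=1, alpha_D=1,
                           lam=0.1, omega=0.1, d=0.3, **kw)

    def test_unaware_population_gives_baseline_beta(self):
        p = self._params()
        state = PopulationState.zeros(5)
        state.set("S", "T", "inf", 0.9)
        state.set("I", "D", "inf", 0.1)
        assert effective_beta(state, p) == pytest.approx(p.beta)

    def test_fully_aware_infected_give_zero(self):
        p = self._params()
        state = PopulationState.zeros(5)
        state.set("S", "T", "inf", 0.9)
        state.set("I", "T", 0, 0.1)
        assert effective_beta(state, p) == 0.0

    def test_two_compartment_value(self):
        # all I and all S at level 1 with rho = 0.5: factor 0.5 * 0.5
        p = self._params(beta=0.667, rho=0.5)
        state = PopulationState.zeros(5)
        state.set("S", "T", 1, 0.9)
        state.set("I", "T", 1, 0.1)
        assert effective_beta(state, p) == pytest.approx(0.667 * 0.25)
        assert effective_R(state, p) == pytest.approx(0.667 * 0.25 / 0.133)

    def test_no_infected_returns_baseline_by_convention(self):
        p = self._params()
        state = PopulationState.zeros(5)
        state.set("S", "T", 2, 1.0)
        assert effective_beta(state, p) == p.beta

    def test_negative_entries_rejected(self):
        p = self._params()
        c = np.zeros((3, 2, 6))
        c[1, 0, 0] = -0.1
        with pytest.raises(ValueError):
            effective_beta(c, p)

    def test_bounded_by_baseline(self):
        rng = np.random.default_rng(7)
        p = self._params(rho=0.9)
        for _ in range(20):
            c = random_state(rng, 5)
            assert 0.0 <= effective_beta(c, p) <= p.beta + 1e-15


class TestAggregate:
    def test_totals_and_level_marginals(self):
        state = PopulationState.zeros(4)
        state.set("S", "T", "inf", 1.0)
        a = state.aggregate()
        assert (a.S, a.I, a.R) == (1.0, 0.0, 0.0)

        state = PopulationState.zeros(4)
        state.set("I", "T", 1, 3.0)
        state.set("I", "D", 1, 4.0)
        a = state.aggregate()
        assert a.I_levels[1] == 7.0
        assert a.t_levels[1] == 3.0 and a.d_levels[1] == 4.0

    def test_sums_conserve_total(self):
        rng = np.random.default_rng(3)
        c = random_state(rng, 6, N=123.0)
        a = PopulationState(c).aggregate()
        assert a.S + a.I + a.R == pytest.approx(123.0, rel=1e-12)


def test_params_validation():
    good = dict(beta=0.5, sigma=0.1, rho=0.5, alpha_T=1, alpha_D=1,
                lam=0.1, omega=0.1, d=0.2)
    ModelParams(**good)
    for bad in [
        dict(good, rho=1.0),
        dict(good, rho=-0.1),
        dict(good, d=1.5),
        dict(good, sigma=0.0),
        dict(good, beta=-1.0),
        dict(good, K=1),
    ]:
        with pytest.raises(ValueError):
            ModelParams(**bad)
    # default truncation keeps protection resolved down to 1e-6
    p = ModelParams(**dict(good, rho=0.9))
    assert 0.9 ** (p.K - 1) < 1e-6 <= 0.9 ** (p.K - 2)
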