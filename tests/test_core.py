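"""Core calculus: strategies, reputation dynamics, Markov chain, payoffs."""

import numpy as np
import pytest
from conftest import random_params, random_state

from trustgame import (
    BUY,
    DISC,
    NOBUY,
    DegenerateChainError,
    GameParams,
    PopulationState,
    buy_probabilities,
    expected_payoffs,
    iterate_reputation,
    markov_eigendecomposition,
    reputation_fixed_point,
    strategy_profile,
    transition_matrix,
)

ALL_BUY = np.array([1.0, 0.0, 0.0, 0.0])
ALL_DISC = np.array([0.0, 1.0, 0.0, 0.0])
ALL_NOBUY = np.array([0.0, 0.0, 0.0, 1.0])


class TestStrategiesAndBuyProbabilities:
    def test_noiseless_corners(self):
        p = strategy_profile(0.0)
        assert np.array_equal(
            p, [[1, 1], [1, 0], [0, 1], [0, 0]]
        ), "Buy, Disc, AntiDisc, NoBuy at eps=0"

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.3, 0.49])
    def test_noisy_profile_bounds(self, eps):
        p = strategy_profile(eps)
        assert np.all((0 <= p) & (p <= 1))
        assert p[DISC, 0] > p[DISC, 1]  # Disc discriminates for eps < 1/2

    def test_pure_population_limits(self):
        params = GameParams(eps=0.0)
        nobuy = buy_probabilities(PopulationState(x=ALL_NOBUY, z=0.5), params)
        assert nobuy.pG == 0.0 and nobuy.pB == 0.0
        buy = buy_probabilities(PopulationState(x=ALL_BUY, z=0.5), params)
        assert buy.pG == 1.0 and buy.pB == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Mixture probabilities equal the explicit strategy-by-reputation sum."""
        params = GameParams(eps=0.2, q=0.35)
        x = rng.dirichlet(np.ones(4))
        y = rng.dirichlet(np.ones(4))
        state = PopulationState(x=x, z=0.5, y=y, allow_asymmetric=True)
        bp = buy_probabilities(state, params)
        p = strategy_profile(params.eps)
        for weights, got_G, got_B in [
            (x, bp.pG_indifferent, bp.pB_indifferent),
            (y, bp.pG_image, bp.pB_image),
        ]:
            exp_G = sum(weights[i] * p[i, 0] for i in range(4))
            exp_B = sum(weights[i] * p[i, 1] for i in range(4))
            assert got_G == pytest.approx(exp_G, abs=1e-15)
            assert got_B == pytest.approx(exp_B, abs=1e-15)
        assert bp.pG == pytest.approx(
            0.65 * bp.pG_indifferent + 0.35 * bp.pG_image, abs=1e-15
        )

    def test_invalid_simplex_reports_component(self):
        with pytest.raises(ValueError, match=r"x\[1\]"):
            PopulationState(x=np.array([0.5, -0.2, 0.4, 0.3]), z=0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationState(x=np.array([0.5, 0.2, 0.2, 0.2]), z=0.5)
        with pytest.raises(ValueError, match="independence"):
            PopulationState(x=ALL_BUY, z=0.5, y=ALL_DISC)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(b=1.2), dict(b=0.0), dict(exploited_payoff=0.5), dict(mu=0.7),
         dict(eps=0.5), dict(q=1.5)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GameParams(**kwargs)


class TestReputationFixedPoint:
    def test_perfect_assignment_scores_cooperators_good(self):
        rep = reputation_fixed_point(
            GameParams(mu=0.0, eps=0.1, q=0.5), PopulationState(x=ALL_BUY, z=0.5)
        )
        assert rep.g_C == pytest.approx(1.0)

    def test_pure_image_scoring_exposes_defectors(self):
        rep = reputation_fixed_point(
            GameParams(mu=0.0, eps=0.1, q=1.0), PopulationState(x=ALL_BUY, z=0.5)
        )
        assert rep.g_D == pytest.approx(0.0)

    def test_closed_form_equals_iteration(self, rng):
        """Closed forms agree with iterating the averaged dynamics from g=0.5."""
        for _ in range(1000):
            params = random_params(rng)
            state = random_state(rng)
            rep = reputation_fixed_point(params, state)
            g_C_it, g_D_it = iterate_reputation(params, state, tol=1e-14)
            assert rep.g_C == pytest.approx(g_C_it, abs=1e-10)
            assert rep.g_D == pytest.approx(g_D_it, abs=1e-10)
            assert 0.0 <= rep.g_D <= rep.g_C <= 1.0

    def test_q_dependence(self, rng):
        """g_C ignores the scorer mix; g_D is non-increasing in it."""
        base = random_params(rng, eps_min=0.05)
        state = random_state(rng, interior=True)
        qs = np.linspace(0.0, 1.0, 41)
        reps = [
            reputation_fixed_point(
                GameParams(b=base.b, exploited_payoff=base.exploited_payoff,
                           mu=base.mu, eps=base.eps, q=float(q)),
                state,
            )
            for q in qs
        ]
        g_C = np.array([r.g_C for r in reps])
        g_D = np.array([r.g_D for r in reps])
        assert np.ptp(g_C) <= 1e-12
        assert np.all(np.diff(g_D) <= 1e-12)


class TestTransitionMatrix:
    def test_row_stochastic_and_consistent_with_fixed_point(self, rng):
        for _ in range(50):
            params = random_params(rng, eps_min=0.02)
            state = random_state(rng, interior=True)
            rep = reputation_fixed_point(params, state)
            for seller, g in (("C", rep.g_C), ("D", rep.g_D)):
                T = transition_matrix(seller, params, state)
                assert np.all(T >= 0) and np.all(T <= 1)
                np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-15)
                # power-iteration oracle for the stationary distribution
                u = np.array([0.5, 0.5])
                for _ in range(2000):
                    u = u @ T
                assert u[0] == pytest.approx(g, abs=1e-9)

    def test_frozen_when_nobody_buys(self):
        params = GameParams(eps=0.0)
        state = PopulationState(x=ALL_NOBUY, z=0.3)
        np.testing.assert_array_equal(transition_matrix("C", params, state), np.eye(2))

    def test_good_reputation_absorbing_for_error_free_cooperator(self):
        params = GameParams(mu=0.0, eps=0.0)
        state = PopulationState(x=ALL_BUY, z=0.3)
        T = transition_matrix("C", params, state)
        assert T[0, 0] == 1.0  # G -> G with certainty


class TestMarkovEigendecomposition:
    def test_degenerate_chain_raises(self):
        with pytest.raises(DegenerateChainError):
            markov_eigendecomposition(np.eye(2))

    @pytest.mark.parametrize("a", [0.1, 0.25, 0.49])
    def test_symmetric_chain_closed_form(self, a):
        T = np.array([[1 - a, a], [a, 1 - a]])
        u, lam, _ = markov_eigendecomposition(T)
        np.testing.assert_allclose(u, [0.5, 0.5])
        assert lam == pytest.approx(1 - 2 * a)

    def test_decomposition_contracts_and_power_limit(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.05, 0.95, size=2)
            T = np.array([[1 - a, a], [b, 1 - b]])
            u, lam, v = markov_eigendecomposition(T)
            assert abs(lam) <= 1.0
            np.testing.assert_allclose(u @ T, u, atol=1e-14)
            assert u.sum() == pytest.approx(1.0)
            w = np.array([1.0, -1.0])
            assert w @ v == pytest.approx(1.0)  # normalization of Perron complement
            assert u @ v == pytest.approx(0.0, abs=1e-15)
            np.testing.assert_allclose(
                np.linalg.matrix_power(T, 200), np.outer(np.ones(2), u), atol=1e-10
            )
            np.testing.assert_allclose(
                T, np.outer(np.ones(2), u) + lam * np.outer(v, w), atol=1e-13
            )


class TestExpectedPayoffs:
    def test_fully_cooperative_limit(self):
        params = GameParams(b=0.7, mu=0.0, eps=0.0)
        prof = expected_payoffs(params, PopulationState(x=ALL_BUY, z=1.0))
        assert prof.buyer[BUY] == pytest.approx(0.7)
        assert prof.seller_C == pytest.approx(0.7)

    def test_fully_exploitative_limit(self):
        params = GameParams(b=0.7, exploited_payoff=-0.4, eps=0.0)
        prof = expected_payoffs(params, PopulationState(x=ALL_BUY, z=0.0))
        assert prof.seller_D == pytest.approx(1.0)
        assert prof.buyer[BUY] == pytest.approx(-0.4)

    def test_nobody_transacts_payoffs_vanish(self):
        prof = expected_payoffs(
            GameParams(eps=0.0), PopulationState(x=ALL_NOBUY, z=0.5)
        )
        assert prof.buyer[NOBUY] == 0.0
        assert prof.seller_C == 0.0 and prof.seller_D == 0.0

    def test_affine_in_seller_fraction_and_frequencies(self, rng):
        """Second differences vanish: payoffs are affine in z and in each x_i."""
        for _ in range(20):
            params = random_params(rng, eps_min=0.02)
            x = rng.dirichlet(np.ones(4))

            def payoffs_at_z(z):
                prof = expected_payoffs(params, PopulationState(x=x, z=z))
                return np.append(prof.buyer, [prof.seller_C, prof.seller_D])

            h = 0.12
            second = payoffs_at_z(0.5 - h) - 2 * payoffs_at_z(0.5) + payoffs_at_z(0.5 + h)
            np.testing.assert_allclose(second, 0.0, atol=1e-12)

            # affine in x along a fixed direction only through the deviator's
            # own mixture: the buyer payoff vector is linear in (p_G, p_B), so
            # a mixed strategy's payoff is the mixture of pure payoffs.
            prof = expected_payoffs(params, PopulationState(x=x, z=0.4))
            mixed = float(x @ prof.buyer)
            assert mixed == pytest.approx(np.dot(x, prof.buyer), abs=1e-15)

    def test_matches_cesaro_average_of_markov_chain(self, rng):
        """Seller payoffs equal the long-run per-game average from matrix powers,
        independent of the initial reputation distribution."""
        for _ in range(5):
            params = random_params(rng, eps_min=0.05, mu_min=0.02)
            state = random_state(rng, interior=True)
            prof = expected_payoffs(params, state)
            rep = prof.reputation
            for seller, expected, scale in (
                ("C", prof.seller_C, params.b),
                ("D", prof.seller_D, 1.0),
            ):
                T = transition_matrix(seller, params, state)
                per_state = scale * np.array([rep.P_G, rep.P_B])
                for u0 in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
                    u, acc = u0.copy(), 0.0
                    n = 20_000
                    for _ in range(n):
                        acc += u @ per_state
                        u = u @ T
                    assert acc / n == pytest.approx(expected, abs=5e-3)
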