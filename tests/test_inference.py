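"""Block coordinate descent driver and partial-problem estimators."""

import numpy as np
import pytest

from lsadmix.inference import (
    estimate_p_known_Q,
    estimate_q_known_P,
    fit,
    init_Q,
    ml_estimate_p_known_Q,
    update_P,
    update_Q,
)
from lsadmix.model import FitConfig, binom_loglik, penalized_objective
from tests.test_solvers import brute_force_bvls, brute_force_simplex


class TestInitQ:
    def test_single_population_is_all_ones(self):
        np.testing.assert_array_equal(init_Q(1, 5, seed=0), np.ones((1, 5)))

    def test_columns_on_simplex(self):
        Q = init_Q(4, 50, seed=3)
        assert Q.min() >= 0
        np.testing.assert_allclose(Q.sum(axis=0), 1.0, atol=1e-12)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(init_Q(3, 10, seed=7), init_Q(3, 10, seed=7))
        assert not np.array_equal(init_Q(3, 10, seed=7), init_Q(3, 10, seed=8))


class TestUpdateP:
    def test_unit_column_design_reads_off_frequencies(self):
        Q = np.eye(2)
        G = np.array([[2, 0]])
        np.testing.assert_allclose(update_P(Q, G), [[1.0, 0.0]], atol=1e-10)

    def test_recovers_truth_on_noiseless_data(self, rng):
        P = rng.random((12, 3))
        Q = rng.dirichlet(np.ones(3), size=9).T
        G = 2 * P @ Q  # real-valued noiseless "genotypes"
        np.testing.assert_allclose(update_P(Q, G), P, atol=1e-8)

    def test_matches_bound_configuration_oracle(self, rng):
        Q = rng.dirichlet(np.ones(2), size=6).T
        G = rng.integers(0, 3, (4, 6))
        P = update_P(Q, G)
        for l in range(4):
            np.testing.assert_allclose(
                P[l], brute_force_bvls(2 * Q.T, G[l].astype(float)), atol=1e-6
            )


class TestUpdateQ:
    def test_dominant_prior_pulls_to_barycentre(self, rng):
        P = rng.random((40, 3))
        G = rng.integers(0, 3, (40, 5))
        Q = update_Q(P, G, alpha=1e6)
        np.testing.assert_allclose(Q, 1 / 3, atol=1e-3)

    def test_recovers_truth_on_noiseless_data(self, rng):
        P = rng.random((60, 3))
        Q = rng.dirichlet(np.ones(3), size=8).T
        G = 2 * P @ Q
        np.testing.assert_allclose(update_Q(P, G, alpha=1.0), Q, atol=1e-6)

    def test_matches_support_enumeration_oracle(self, rng):
        from lsadmix.solvers import build_normal_equations

        P = rng.random((30, 3))
        G = rng.integers(0, 3, (30, 6))
        Q = update_Q(P, G, alpha=1.0)
        ne = build_normal_equations(P, G.astype(float), 1.0)
        for i in range(6):
            np.testing.assert_allclose(Q[:, i], brute_force_simplex(ne.gram, ne.rhs[:, i]), atol=1e-6)


class TestFit:
    def test_zero_residual_recovery_up_to_permutation(self, rng):
        # pure individuals, frequencies in {0,1}: exact factorisation exists
        M, N, K = 40, 30, 3
        P = rng.integers(0, 2, (M, K)).astype(float)
        while np.linalg.matrix_rank(P) < K:  # pragma: no cover
            P = rng.integers(0, 2, (M, K)).astype(float)
        labels = rng.integers(0, K, N)
        labels[:K] = np.arange(K)  # every population represented
        Q = np.zeros((K, N))
        Q[labels, np.arange(N)] = 1.0
        G = (2 * P @ Q).astype(int)

        successes = 0
        for seed in range(5):
            res = fit(G, FitConfig(K=K, seed=seed, max_iter=300))
            trace = np.array(res.objective_trace)
            assert np.all(np.diff(trace) <= 1e-6 * np.maximum(1.0, np.abs(trace[:-1])))
            if trace[-1] <= 1e-6:
                successes += 1
                from lsadmix.evaluate import align_populations

                perm = list(align_populations(res.Q, Q))
                np.testing.assert_allclose(res.Q[perm], Q, atol=1e-4)
                np.testing.assert_allclose(res.P[:, perm], P, atol=1e-4)
        assert successes >= 1

    def test_single_population_closed_form(self, rng):
        G = rng.integers(0, 3, (20, 8))
        res = fit(G, FitConfig(K=1, seed=0))
        np.testing.assert_array_equal(res.Q, np.ones((1, 8)))
        np.testing.assert_allclose(res.P[:, 0], np.clip(G.mean(axis=1) / 2, 0, 1), atol=1e-10)

    def test_huge_epsilon_stops_immediately_converged(self, rng):
        G = rng.integers(0, 3, (10, 6))
        res = fit(G, FitConfig(K=2, epsilon=1e10, seed=0))
        assert res.converged
        assert res.n_iter >= 1
        assert res.n_iter <= 2

    def test_max_iter_reports_nonconvergence(self, rng):
        G = rng.integers(0, 3, (30, 20))
        res = fit(G, FitConfig(K=2, epsilon=1e-300, max_iter=3, seed=0))
        assert not res.converged
        assert res.n_iter == 3

    def test_objective_monotone_on_random_data(self, rng):
        G = rng.binomial(2, 0.4, (50, 25))
        for alpha in (0.5, 1.0, 2.0):
            res = fit(G, FitConfig(K=3, alpha=alpha, seed=1, max_iter=50))
            trace = np.array(res.objective_trace)
            assert np.all(np.diff(trace) <= 1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_converged_fixed_point(self, rng):
        G = rng.binomial(2, 0.5, (40, 15))
        cfg = FitConfig(K=2, seed=2, max_iter=500)
        res = fit(G, cfg)
        assert res.converged
        # one extra sweep moves the criterion by less than epsilon
        P2 = update_P(res.Q, G.astype(float))
        Q2 = update_Q(P2, G.astype(float), 1.0)
        obj2 = penalized_objective(P2, Q2, G, 1.0)
        assert abs(obj2 - res.objective_trace[-1]) < cfg.resolve_epsilon(*G.shape)

    def test_individual_permutation_equivariance(self, rng):
        # permuting individuals and the initial simplex columns together
        # permutes every subsequent iterate identically
        G = rng.binomial(2, 0.5, (30, 12))
        perm = rng.permutation(12)
        Q0 = init_Q(2, 12, seed=5)
        Qa, Qb = Q0.copy(), Q0[:, perm].copy()
        Ga, Gb = G.astype(float), G[:, perm].astype(float)
        for _ in range(3):
            Pa, Pb = update_P(Qa, Ga), update_P(Qb, Gb)
            Qa, Qb = update_Q(Pa, Ga, 1.0), update_Q(Pb, Gb, 1.0)
        np.testing.assert_allclose(Qa[:, perm], Qb, atol=1e-10)
        np.testing.assert_allclose(Pa, Pb, atol=1e-10)

    def test_rejects_more_populations_than_individuals(self, rng):
        G = rng.integers(0, 3, (10, 2))
        with pytest.raises(ValueError, match="individuals"):
            fit(G, FitConfig(K=3))


class TestKnownFactorEstimators:
    def test_p_known_Q_exact_on_noiseless_data(self, rng):
        P = rng.random((15, 2))
        Q = rng.dirichlet([1, 1], size=10).T
        G = 2 * P @ Q
        np.testing.assert_allclose(estimate_p_known_Q(G, Q), P, atol=1e-10)

    def test_p_known_Q_single_population_is_half_mean(self, rng):
        G = rng.integers(0, 3, (6, 20)).astype(float)
        Q = np.ones((1, 20))
        np.testing.assert_allclose(estimate_p_known_Q(G, Q)[:, 0], G.mean(axis=1) / 2)

    def test_p_known_Q_matches_per_locus_normal_equations(self, rng):
        Q = rng.dirichlet(np.ones(3), size=20).T
        G = rng.integers(0, 3, (8, 20)).astype(float)
        P = estimate_p_known_Q(G, Q)
        for l in range(8):
            expected = 0.5 * np.linalg.solve(Q @ Q.T, Q @ G[l])
            np.testing.assert_allclose(P[l], expected, atol=1e-10)

    def test_p_known_Q_is_unconstrained_by_default(self):
        # nearly collinear individuals drive the estimate far outside [0,1]:
        # QQ' = [[.505,.495],[.495,.505]], g = (2,0) gives p-hat = (5.5, -4.5)
        Q = np.array([[0.55, 0.45], [0.45, 0.55]])
        G = np.array([[2.0, 0.0]])
        P = estimate_p_known_Q(G, Q)
        np.testing.assert_allclose(P[0], [5.5, -4.5], atol=1e-9)
        Pc = estimate_p_known_Q(G, Q, clamp=True)
        np.testing.assert_allclose(Pc[0], [1.0, 0.0], atol=1e-12)

    def test_q_known_P_exact_on_noiseless_data(self, rng):
        P = rng.random((60, 3))
        Q = rng.dirichlet(np.ones(3), size=7).T
        G = 2 * P @ Q
        np.testing.assert_allclose(estimate_q_known_P(G, P), Q, atol=1e-6)

    def test_q_known_P_orthogonal_design_closed_form(self, rng):
        # orthogonal design: half the loci are fixed (1,0), half (0,1), so
        # the criterion separates into (q1 - a)^2 + (q2 - b)^2 with
        # a = mean(g_pop1)/2, b = mean(g_pop2)/2, and the simplex solution
        # is the equality-constrained projection clipped to [0, 1]
        M, N = 30, 10
        P = np.zeros((2 * M, 2))
        P[:M, 0] = 1.0
        P[M:, 1] = 1.0
        G = rng.integers(0, 3, (2 * M, N))
        Q = estimate_q_known_P(G, P, alpha=1.0)
        a = G[:M].mean(axis=0) / 2
        b = G[M:].mean(axis=0) / 2
        q1 = np.clip(a + (1 - a - b) / 2, 0, 1)
        np.testing.assert_allclose(Q[0], q1, atol=1e-8)
        np.testing.assert_allclose(Q.sum(axis=0), 1.0, atol=1e-12)


class TestMlEstimator:
    def test_all_twos_push_to_one(self):
        Q = np.array([[0.6, 0.3], [0.4, 0.7]])
        G = np.array([[2, 2]])
        np.testing.assert_allclose(ml_estimate_p_known_Q(G, Q, 0), [1.0, 1.0], atol=1e-6)

    def test_single_population_matches_binomial_mle(self, rng):
        G = rng.integers(0, 3, (1, 50))
        Q = np.ones((1, 50))
        p = ml_estimate_p_known_Q(G, Q, 0)
        assert p[0] == pytest.approx(G.mean() / 2, abs=1e-6)

    def test_matches_grid_search(self, rng):
        N = 8
        Q = rng.dirichlet([1, 1], size=N).T
        G = rng.binomial(2, np.array([0.3, 0.8]) @ Q)[None, :]
        p_hat = ml_estimate_p_known_Q(G, Q, 0)
        grid = np.linspace(0, 1, 1001)
        P1, P2 = np.meshgrid(grid, grid, indexing="ij")
        m = P1[..., None] * Q[0] + P2[..., None] * Q[1]
        m = np.clip(m, 1e-10, 1 - 1e-10)
        g = G[0].astype(float)
        ll = np.sum(g * np.log(m) + (2 - g) * np.log(1 - m), axis=-1)
        best = np.unravel_index(np.argmax(ll), ll.shape)
        np.testing.assert_allclose(p_hat, [grid[best[0]], grid[best[1]]], atol=2e-3)

    def test_never_below_least_squares_likelihood(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            Q = r.dirichlet([1, 1], size=40).T
            G = r.binomial(2, np.array([0.4, 0.6]) @ Q)[None, :]
            p_ml = ml_estimate_p_known_Q(G, Q, 0)
            p_ls = estimate_p_known_Q(G, Q, clamp=True)[0]
            ll_ml = binom_loglik(p_ml[None, :], Q, G)
            ll_ls = binom_loglik(p_ls[None, :], Q, G)
            assert ll_ml >= ll_ls - 1e-9
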