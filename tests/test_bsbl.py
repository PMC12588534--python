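"""Posterior/cost oracles, hyperparameter updates and the fitting variants."""

import numpy as np
import pytest

from m6afuzzy import (
    BsblOptions,
    cost,
    fit_bsbl,
    fit_ls,
    fit_sbl,
    gen_block_sparse,
    posterior,
    predict,
    update_hyperparameters,
)
from m6afuzzy.bsbl import singleton_block_map
from m6afuzzy.evaluation import auc_score


def brute_posterior(X, y, Gamma, beta):
    """Dense textbook evaluation with explicit inverses (oracle)."""
    Sigma = np.linalg.inv(np.linalg.inv(Gamma) + beta * X.T @ X)
    mu = beta * Sigma @ X.T @ y
    return mu, Sigma


def random_instance(rng, N=None, D=None):
    N = N or rng.integers(5, 41)
    D = D or rng.integers(2, 41)
    X = rng.normal(size=(N, D))
    y = rng.normal(size=N)
    A = rng.normal(size=(D, D))
    Gamma = A @ A.T + D * np.eye(D)  # comfortably PD
    beta = float(rng.uniform(0.1, 10.0))
    return X, y, Gamma, beta


class TestPosterior:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            X, y, Gamma, beta = random_instance(rng)
            mu, Sigma = posterior(X, y, Gamma, beta)
            mu_o, Sigma_o = brute_posterior(X, y, Gamma, beta)
            assert np.linalg.norm(mu - mu_o) <= 1e-8 * max(np.linalg.norm(mu_o), 1)
            assert np.linalg.norm(Sigma - Sigma_o) <= 1e-8 * np.linalg.norm(Sigma_o)

    def test_primal_and_dual_forms_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X, y, Gamma, beta = random_instance(rng)
            mu_p, Sig_p = posterior(X, y, Gamma, beta, form="primal")
            mu_d, Sig_d = posterior(X, y, Gamma, beta, form="dual")
            assert np.allclose(mu_p, mu_d, atol=1e-8, rtol=1e-8)
            assert np.allclose(Sig_p, Sig_d, atol=1e-8, rtol=1e-8)

    def test_noiseless_limit_interpolates(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=8)
        mu, _ = posterior(np.eye(8), y, np.eye(8), beta=1e12)
        assert np.max(np.abs(mu - y)) < 1e-6

    def test_ridge_equivalence(self):
        """Gamma = (1/(lambda*beta)) I makes the posterior mean the ridge solution."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        lam, beta = 0.5, 2.0
        mu, _ = posterior(X, y, np.eye(12) / (lam * beta), beta)
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(12), X.T @ y)
        assert np.allclose(mu, ridge, atol=1e-10)

    def test_vanishing_prior_shrinks_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        for eps in (1e-4, 1e-7):
            mu, _ = posterior(X, y, eps * np.eye(6), beta=1.0)
            assert np.linalg.norm(mu) < 20 * eps * np.linalg.norm(X.T @ y)


class TestCost:
    def test_identity_covariance_zero_target(self):
        X = np.zeros((5, 3))
        assert cost(np.zeros(5), np.eye(3), beta=1.0, design=X) == pytest.approx(0.0)

    def test_identity_covariance_norm_five(self):
        X = np.zeros((5, 3))
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        assert cost(y, np.eye(3), 1.0, X) == pytest.approx(5.0)

    def test_matches_explicit_logdet_plus_quadratic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X, y, Gamma, beta = random_instance(rng, N=int(rng.integers(5, 31)))
            C = np.eye(len(y)) / beta + X @ Gamma @ X.T
            expected = float(np.linalg.slogdet(C)[1] + y @ np.linalg.inv(C) @ y)
            assert cost(y, Gamma, beta, X) == pytest.approx(expected, rel=1e-8)


class TestHyperparameterUpdates:
    def test_gamma_fixed_point_when_no_data_support(self):
        """mu_i = 0 and Sigma_i = gamma_i B_i leave gamma_i exactly unchanged."""
        rng = np.random.default_rng(6)
        sizes = [3, 4]
        block_map = [slice(0, 3), slice(3, 7)]
        gammas = np.array([0.7, 2.5])
        Bs = []
        Sigma = np.zeros((7, 7))
        for g, sl, d in zip(gammas, block_map, sizes):
            A = rng.normal(size=(d, d))
            B = A @ A.T + d * np.eye(d)
            B /= np.trace(B) / d
            Bs.append(B)
            Sigma[sl, sl] = g * B
        X = rng.normal(size=(12, 7))
        y = rng.normal(size=12)
        opts = BsblOptions(correlation_constraint="none")
        gamma_new, _, _ = update_hyperparameters(
            np.zeros(7), Sigma, X, y, block_map, opts, B=Bs
        )
        assert np.max(np.abs(gamma_new - gammas)) < 1e-12

    def test_beta_update_on_exact_fit(self):
        """With y = X mu the residual vanishes and beta = N / Tr[Sigma X^T X]."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 4))
        mu = rng.normal(size=4)
        y = X @ mu
        A = rng.normal(size=(4, 4))
        Sigma = A @ A.T + np.eye(4)
        t = float(np.sum(Sigma * (X.T @ X)))
        _, _, beta = update_hyperparameters(
            mu, Sigma, X, y, [slice(0, 4)], BsblOptions(correlation_constraint="none")
        )
        assert beta == pytest.approx(10.0 / t, rel=1e-12)

    def test_two_block_step_matches_independent_expansion(self):
        """One update step equals a scripted elementwise expansion of the
        gamma / B / beta formulas."""
        rng = np.random.default_rng(8)
        block_map = [slice(0, 3), slice(3, 6)]
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        mu = rng.normal(size=6)
        A = rng.normal(size=(6, 6))
        Sigma = A @ A.T + np.eye(6)
        Bs = [np.eye(3), np.eye(3)]
        gamma_new, B_new, beta = update_hyperparameters(
            mu, Sigma, X, y, block_map, BsblOptions(correlation_constraint="none"), B=Bs
        )
        # independent expansion, scalar loops only
        for i, sl in enumerate(block_map):
            mu_i = mu[sl]
            S_i = Sigma[sl, sl] + np.outer(mu_i, mu_i)
            g_expect = np.trace(np.linalg.inv(Bs[i]) @ S_i) / 3.0
            assert gamma_new[i] == pytest.approx(g_expect, rel=1e-12)
            assert np.allclose(B_new[i], S_i / g_expect, atol=1e-12)
        resid = y - X @ mu
        denom = resid @ resid + np.trace(Sigma @ X.T @ X)
        assert beta == pytest.approx(12.0 / denom, rel=1e-12)

    def test_sbl_gamma_update_is_sigma_plus_mu_squared(self):
        """Singleton blocks reduce the gamma update to Sigma_ii + mu_i^2."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        mu = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + np.eye(3)
        gamma_new, _, _ = update_hyperparameters(
            mu, Sigma, X, y, singleton_block_map(3),
            BsblOptions(correlation_constraint="none"),
        )
        assert np.allclose(gamma_new, np.diag(Sigma) + mu**2, atol=1e-12)


class TestFitBsbl:
    def test_recovers_block_support_and_coefficients(self):
        prob = gen_block_sparse(
            N=150, M=20, block_size=4, k_active=3, intra_block_r=0.9,
            snr_db=25.0, seed=42,
        )
        model = fit_bsbl(prob.design, prob.y, block_map=prob.block_map)
        assert set(model.active_blocks) == set(prob.active_blocks)
        rel = np.linalg.norm(model.mu - prob.p_true) / np.linalg.norm(prob.p_true)
        assert rel < 0.05

    def test_zero_targets_give_zero_mean_and_shrinking_gamma(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 8))
        model = fit_bsbl(
            X, np.zeros(20),
            options=BsblOptions(max_iter=30),
            block_map=[slice(0, 4), slice(4, 8)],
        )
        assert np.allclose(model.mu, 0.0, atol=1e-12)
        assert np.all(model.gamma <= 1.0)

    def test_row_order_invariance(self):
        prob = gen_block_sparse(N=60, M=5, block_size=3, k_active=2, seed=11)
        m1 = fit_bsbl(prob.design, prob.y, block_map=prob.block_map)
        perm = np.random.default_rng(0).permutation(60)
        m2 = fit_bsbl(prob.design[perm], prob.y[perm], block_map=prob.block_map)
        assert np.allclose(m1.mu, m2.mu, atol=1e-8)

    def test_not_converged_is_flagged_not_raised(self):
        prob = gen_block_sparse(N=40, M=4, block_size=3, k_active=2, seed=12)
        model = fit_bsbl(
            prob.design, prob.y,
            options=BsblOptions(max_iter=2, eta=1e-12),
            block_map=prob.block_map,
        )
        assert not model.converged and model.iterations == 2

    def test_cost_trace_monotone_for_literal_updates(self):
        """The unconstrained (printed) update sequence never increases the
        type-II cost beyond numerical tolerance on well-posed problems."""
        bad = 0
        for seed in range(20):
            prob = gen_block_sparse(
                N=150, M=20, block_size=4, k_active=3, intra_block_r=0.9,
                snr_db=25.0, seed=seed,
            )
            model = fit_bsbl(
                prob.design, prob.y,
                options=BsblOptions(correlation_constraint="none"),
                block_map=prob.block_map,
            )
            if np.any(np.diff(model.cost_trace) > 1e-6):
                bad += 1
        assert bad <= 1  # >= 95% of seeded runs are non-increasing


class TestSblAndLs:
    def test_sbl_equals_bsbl_with_singleton_blocks_bitwise(self):
        prob = gen_block_sparse(N=50, M=6, block_size=2, k_active=2, seed=13)
        m_sbl = fit_sbl(prob.design, prob.y)
        m_bsbl = fit_bsbl(
            prob.design, prob.y, block_map=singleton_block_map(12)
        )
        assert np.array_equal(m_sbl.mu, m_bsbl.mu)
        assert np.array_equal(m_sbl.gamma, m_bsbl.gamma)
        assert m_sbl.beta == m_bsbl.beta

    def test_sbl_zero_targets(self):
        X = np.random.default_rng(14).normal(size=(15, 5))
        model = fit_sbl(X, np.zeros(15), options=BsblOptions(max_iter=20))
        assert np.allclose(model.mu, 0.0, atol=1e-12)

    def test_ls_large_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        assert np.linalg.norm(fit_ls(X, y, ridge_lambda=1e12).mu) < 1e-9

    def test_ls_zero_lambda_square_invertible(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(6, 6))
        y = rng.normal(size=6)
        assert np.allclose(fit_ls(X, y, ridge_lambda=0.0).mu, np.linalg.solve(X, y))

    def test_ls_zero_lambda_rank_deficient_minimum_norm(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(5, 10))  # underdetermined
        y = rng.normal(size=5)
        mu = fit_ls(X, y, ridge_lambda=0.0).mu
        expected, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(mu, expected)

    def test_ls_matches_posterior_under_matched_prior(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        lam, beta = 0.5, 3.0
        mu_post, _ = posterior(X, y, np.eye(12) / (lam * beta), beta)
        assert np.allclose(fit_ls(X, y, ridge_lambda=lam).mu, mu_post, atol=1e-10)


class TestPredict:
    def _toy_model(self, mu, D, beta=1.0, Sigma=None):
        from m6afuzzy.bsbl import BsblModel

        return BsblModel(
            mu=np.asarray(mu, dtype=float),
            Sigma=Sigma,
            gamma=None,
            B=None,
            beta=beta,
            block_map=[slice(0, D)],
            iterations=1,
            converged=True,
        )

    def test_zero_mean_gives_half_probability_negative_label(self):
        model = self._toy_model(np.zeros(4), 4)
        X = np.random.default_rng(19).normal(size=(6, 4))
        out = predict(model, X)
        assert np.all(out.score == 0.0)
        assert np.allclose(out.probability, 0.5)
        assert np.all(out.label == -1)

    def test_positive_scaling_preserves_labels(self):
        rng = np.random.default_rng(20)
        mu = rng.normal(size=5)
        X = rng.normal(size=(10, 5))
        out1 = predict(self._toy_model(mu, 5), X)
        out2 = predict(self._toy_model(3.0 * mu, 5), X)
        assert np.allclose(out2.score, 3.0 * out1.score)
        assert np.array_equal(out1.label, out2.label)

    def test_separable_training_scores_reach_auc_one(self):
        """Noiseless targets are recovered exactly, so scores rank the sign
        labels perfectly."""
        prob = gen_block_sparse(N=80, M=4, block_size=3, k_active=4, snr_db=None, seed=21)
        labels = np.where(prob.y > 0, 1, -1)
        model = fit_bsbl(prob.design, prob.y, block_map=prob.block_map)
        out = predict(model, prob.design)
        assert auc_score(labels, out.score) == 1.0

    def test_width_mismatch_rejected(self):
        model = self._toy_model(np.zeros(4), 4)
        with pytest.raises(ValueError, match="width"):
            predict(model, np.zeros((3, 5)))

    def test_probabilities_strictly_inside_unit_interval(self):
        model = self._toy_model([100.0], 1, beta=1e6)
        out = predict(model, np.array([[1e3], [-1e3]]))
        assert np.all(out.probability > 0.0) and np.all(out.probability < 1.0)
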