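"""Estimation core: alpha regression against an OLS oracle, adjustment
identities, moment estimators, the penalized coordinate-descent
discriminant against direct-solve / QP / closed-form oracles, the covariate
LDA, and the intercept identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from catchmsi import core
from conftest import random_spd


def labels_half(n):
    y = np.ones(n, dtype=int)
    y[n // 2:] = 2
    return y


# ---------------------------------------------------------------- alpha


class TestEstimateAlpha:
    def test_constant_within_class_gives_zero(self, rng):
        n = 40
        y = labels_half(n)
        tensors = np.where((y == 2)[:, None, None], 1.0, -1.0) * np.ones((n, 2, 2))
        G = rng.standard_normal((n, 3))
        alpha = core.estimate_alpha(tensors, G, y)
        assert np.allclose(alpha, 0.0, atol=1e-12)

    def test_noiseless_line_recovered_exactly(self, rng):
        n = 30
        y = labels_half(n)
        G = rng.standard_normal((n, 1))
        tensors = (2.0 * G[:, 0] + np.where(y == 2, 5.0, -5.0)).reshape(n, 1, 1)
        alpha = core.estimate_alpha(tensors, G, y)
        assert alpha[0, 0, 0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_per_cell_ols_oracle(self, rng):
        """Brute-force oracle: per-cell multivariate OLS (lstsq) on
        class-centered data."""
        n, q, d = 50, 3, 2
        y = labels_half(n)
        G = rng.standard_normal((n, q))
        tensors = rng.standard_normal((n, d, d))
        alpha = core.estimate_alpha(tensors, G, y)

        Gc = G.copy()
        Mc = tensors.reshape(n, -1).copy()
        for k in (1, 2):
            Gc[y == k] -= Gc[y == k].mean(axis=0)
            Mc[y == k] -= Mc[y == k].mean(axis=0)
        for cell in range(d * d):
            beta, *_ = np.linalg.lstsq(Gc, Mc[:, cell], rcond=None)
            assert np.allclose(alpha.reshape(-1, q)[cell], beta, atol=1e-8)

    def test_n_le_q_guard(self, rng):
        y = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError, match="ridge"):
            core.estimate_alpha(rng.standard_normal((4, 1, 1)),
                                rng.standard_normal((4, 5)), y)


class TestAdjust:
    def test_alpha_zero_is_identity(self, rng):
        tensors = rng.standard_normal((5, 2, 3))
        G = rng.standard_normal((5, 2))
        out = core.adjust(tensors, G, np.zeros((2, 3, 2)))
        assert np.array_equal(out, tensors)

    def test_hand_arithmetic(self):
        tensors = np.ones((1, 2, 2))
        G = np.array([[2.0]])
        alpha = np.ones((2, 2, 1))
        out = core.adjust(tensors, G, alpha)
        assert np.allclose(out, -1.0)  # every cell reduced by 2

    def test_true_alpha_removes_covariate_slope(self):
        """Adjusting with the generating alpha leaves cells uncorrelated
        with G within class."""
        from catchmsi.synthetic import SimulationConfig, generate_cohort

        cfg = SimulationConfig(n_cases=500, control_ratio=3, d1=2, d2=2,
                               q=2, s=1, delta=1.0, alpha_density=1.0,
                               alpha_scale=0.6, covariate_shift=1.0, seed=8)
        cohort, truth = generate_cohort(cfg)
        n = cohort.n_samples
        M = cohort.metabolites.to_numpy().reshape(n, 2, 2)
        G = cohort.covariates.to_numpy()
        adj = core.adjust(M, G, truth.alpha_true)
        y = cohort.labels.to_numpy()
        slopes = core.estimate_alpha(adj, G, y)
        # slope CI ~ 1/sqrt(n) per entry; 5 sigma bound
        assert np.abs(slopes).max() < 5.0 / np.sqrt(n)


class TestMoments:
    def test_identity_covariance_recovered(self, rng):
        n, d = 5000, 3
        y = labels_half(n)
        tensors = rng.standard_normal((n, d, d))
        mu1, mu2, s1, s2, priors = core.estimate_moments(tensors, y)
        assert np.linalg.norm(s1 - np.eye(d)) < 0.1
        assert np.linalg.norm(s2 - np.eye(d)) < 0.1
        assert s1[0, 0] == 1.0
        assert priors == (0.5, 0.5)

    def test_ar1_pattern_recovered(self):
        """Off-diagonal decay of AR(1) mode covariances is recovered with
        the right sign across seeds."""
        from catchmsi.synthetic import SimulationConfig, generate_cohort

        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_cases=250, control_ratio=1, d1=3, d2=3,
                                   q=2, s=1, delta=0.5, alpha_scale=0.0,
                                   alpha_density=0.0, covariate_shift=0.0,
                                   rho1=0.5, rho2=0.5, seed=seed)
            cohort, _ = generate_cohort(cfg)
            n = cohort.n_samples
            M = cohort.metabolites.to_numpy().reshape(n, 3, 3)
            y = cohort.labels.to_numpy()
            _, _, s1, s2, _ = core.estimate_moments(M, y)
            rho1_hat = (s1[0, 1] + s1[1, 2]) / 2
            rho2_hat = (s2[0, 1] / s2[0, 0] + s2[1, 2] / s2[1, 1]) / 2
            hits += (rho1_hat > 0.3) and (rho2_hat > 0.3)
        assert hits >= 9

    def test_kronecker_scale_is_consistent(self, rng):
        """sigma1 (x) sigma2 recovers the full covariance scale even when
        the row covariance does not have unit trace."""
        n, d = 4000, 2
        y = labels_half(n)
        S1 = np.array([[4.0, 1.0], [1.0, 2.0]])
        S2 = np.array([[1.0, 0.3], [0.3, 1.0]])
        L1, L2 = np.linalg.cholesky(S1), np.linalg.cholesky(S2)
        Z = rng.standard_normal((n, d, d))
        tensors = np.einsum("ik,nkl,jl->nij", L1, Z, L2)
        _, _, s1, s2, _ = core.estimate_moments(tensors, y)
        kron_hat = np.kron(s1, s2)
        kron_true = np.kron(S1, S2)
        assert np.linalg.norm(kron_hat - kron_true) / np.linalg.norm(kron_true) < 0.1

    def test_degenerate_residuals_guard(self):
        tensors = np.tile(np.ones((1, 2, 2)), (6, 1, 1))
        y = labels_half(6)
        with pytest.raises(ValueError, match="degenerate"):
            core.estimate_moments(tensors, y)

    def test_single_sample_class_rejected(self, rng):
        tensors = rng.standard_normal((3, 2, 2))
        with pytest.raises(ValueError, match="at least 2"):
            core.estimate_moments(tensors, np.array([1, 1, 2]))


# ------------------------------------------------- sparse discriminant


class TestSparseDiscriminant:
    def test_kkt_zero_above_lambda_max(self, rng):
        s1, s2 = random_spd(rng, 3), random_spd(rng, 3)
        mu1, mu2 = rng.standard_normal((3, 3)), rng.standard_normal((3, 3))
        lam = core.lambda_max(mu1, mu2)
        B = core.solve_sparse_discriminant(mu1, mu2, s1, s2, lam)
        assert np.all(B == 0.0)

    def test_lambda_zero_matches_direct_solve(self, rng):
        for _ in range(10):
            s1, s2 = random_spd(rng, 3), random_spd(rng, 3)
            mu1 = rng.standard_normal((3, 3))
            mu2 = rng.standard_normal((3, 3))
            B = core.solve_sparse_discriminant(mu1, mu2, s1, s2, 0.0)
            oracle = np.linalg.solve(s1, np.linalg.solve(s2, (mu2 - mu1).T).T)
            assert np.abs(B - oracle).max() < 1e-6

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_identity_covariances_soft_threshold(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.standard_normal((3, 4))
        lam = float(rng.uniform(0, 1.5))
        B = core.solve_sparse_discriminant(np.zeros((3, 4)), D, np.eye(3),
                                           np.eye(4), lam)
        expected = np.sign(D) * np.maximum(np.abs(D) - lam, 0.0)
        assert np.allclose(B, expected, atol=1e-10)

    def test_objective_non_increasing_every_sweep(self, rng):
        s1, s2 = random_spd(rng, 4), random_spd(rng, 4)
        mu2 = rng.standard_normal((4, 4))
        _, info = core.solve_sparse_discriminant(
            np.zeros((4, 4)), mu2, s1, s2, 0.1, return_info=True)
        obj = np.array(info["objective"])
        assert np.all(np.diff(obj) <= 1e-12)

    def test_l1_norm_monotone_in_penalty(self, rng):
        s1, s2 = random_spd(rng, 3), random_spd(rng, 3)
        mu2 = rng.standard_normal((3, 3))
        lmax = core.lambda_max(np.zeros((3, 3)), mu2)
        norms = []
        for lam in np.linspace(lmax, 0, 8):
            B = core.solve_sparse_discriminant(np.zeros((3, 3)), mu2, s1,
                                               s2, lam)
            norms.append(np.abs(B).sum())
        assert all(a <= b + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_masked_cells_pinned_at_zero(self, rng):
        s1, s2 = random_spd(rng, 3), random_spd(rng, 3)
        mu2 = rng.standard_normal((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[2, 2] = True
        B = core.solve_sparse_discriminant(np.zeros((3, 3)), mu2, s1, s2,
                                           0.01, mask=mask)
        assert B[2, 2] == 0.0

    def test_non_pd_covariance_rejected(self, rng):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError, match="positive definite"):
            core.solve_sparse_discriminant(np.zeros((2, 2)),
                                           np.ones((2, 2)), bad, np.eye(2),
                                           0.1)

    def test_vector_case_matches_qp_oracle(self, rng):
        """d2 = 1 reduces to plain sparse LDA; cross-check against an
        independent quadratic-program solve (split positive/negative
        parts, L-BFGS-B) on 6-dim instances."""
        d = 6
        for trial in range(5):
            S = random_spd(rng, d, jitter=4.0)
            delta = rng.standard_normal(d)
            lam = 0.3
            B = core.solve_sparse_discriminant(
                np.zeros((d, 1)), delta.reshape(d, 1), S, np.eye(1), lam,
                tol=1e-12)

            def fg(z):
                u, v = z[:d], z[d:]
                b = u - v
                Sb = S @ b
                f = 0.5 * b @ Sb - delta @ b + lam * (u.sum() + v.sum())
                g = np.concatenate([Sb - delta + lam, -(Sb - delta) + lam])
                return f, g

            res = minimize(fg, np.zeros(2 * d), jac=True, method="L-BFGS-B",
                           bounds=[(0, None)] * 2 * d,
                           options={"maxiter": 50_000, "ftol": 1e-16,
                                    "gtol": 1e-12})
            oracle = res.x[:d] - res.x[d:]
            assert np.abs(B[:, 0] - oracle).max() < 1e-6


# ------------------------------------------------- covariate LDA, intercept


class TestCovariateDiscriminant:
    def test_equal_means_give_zero(self, rng):
        G = rng.standard_normal((40, 3))
        G = np.vstack([G, G])
        y = labels_half(80)
        gamma, phi1, phi2, _ = core.fit_covariate_discriminant(G, y)
        assert np.allclose(phi1, phi2)
        assert np.allclose(gamma, 0.0, atol=1e-12)

    def test_scalar_arithmetic(self):
        # q=1, pooled variance 2, mean difference 4 -> gamma = 2
        # each class: centered [-2,-1,1,2]*c, SS = 10 c^2; pooled over both
        # classes with denominator n-2 = 6: Psi = 20 c^2 / 6 = 2 at c^2 = 0.6
        x1 = np.array([-2.0, -1.0, 1.0, 2.0]) * np.sqrt(0.6)
        x2 = x1 + 4.0
        G = np.concatenate([x1, x2]).reshape(-1, 1)
        y = labels_half(8)
        gamma, *_ = core.fit_covariate_discriminant(G, y)
        assert gamma[0] == pytest.approx(2.0)

    def test_direction_matches_sklearn_lda(self, rng):
        """Same discriminant direction as generic LDA on the covariates
        alone (scale conventions differ; the ratio must be constant)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        n, q = 120, 4
        y = labels_half(n)
        G = rng.standard_normal((n, q)) + np.where(y == 2, 0.8, 0.0)[:, None]
        gamma, *_ = core.fit_covariate_discriminant(G, y)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(G, y)
        ratio = gamma / lda.coef_[0]
        assert np.allclose(ratio, ratio[0], atol=1e-8)

    def test_singular_psi_needs_ridge(self, rng):
        G = np.repeat(rng.standard_normal((30, 1)), 3, axis=1)  # rank 1
        y = labels_half(30)
        with pytest.raises(np.linalg.LinAlgError):
            core.fit_covariate_discriminant(G, y)
        gamma, *_ = core.fit_covariate_discriminant(G, y, ridge=1e-6)
        assert np.isfinite(gamma).all()


class TestIntercept:
    def test_symmetry_gives_zero(self):
        B = np.ones((2, 2))
        mu = np.ones((2, 2)) * 0.7
        a2 = core.compute_intercept(B, -mu, mu, np.zeros(0), np.zeros(0),
                                    np.zeros(0), (0.5, 0.5))
        assert a2 == pytest.approx(0.0)

    def test_prior_only_closed_form(self):
        a2 = core.compute_intercept(np.zeros((2, 2)), np.zeros((2, 2)),
                                    np.zeros((2, 2)), np.zeros(3),
                                    np.zeros(3), np.zeros(3), (0.75, 0.25))
        assert a2 == pytest.approx(np.log(1 / 3))

    def test_zero_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            core.compute_intercept(np.zeros((1, 1)), np.zeros((1, 1)),
                                   np.zeros((1, 1)), np.zeros(0),
                                   np.zeros(0), np.zeros(0), (1.0, 0.0))

    def test_midpoint_score_equals_log_prior_ratio(self, small_cohort):
        """Plug-in identity: at the exact midpoint of the fitted class
        means the score is log(pi2/pi1)."""
        from catchmsi.model import CatchClassifier

        cohort, _ = small_cohort
        clf = CatchClassifier(d1=4, d2=4, n_covariates=5, penalty=0.05)
        clf.fit(cohort.design_matrix(), cohort.labels)
        mid_adj = (clf.mu1_ + clf.mu2_) / 2
        mid_phi = (clf.phi1_ + clf.phi2_) / 2
        # build a raw tensor whose adjusted version is exactly mid_adj
        M = mid_adj + np.einsum("ijg,g->ij", clf.alpha_, mid_phi)
        score = core.catch_score(M[None], mid_phi[None], clf.alpha_, clf.B_,
                                 clf.gamma_, clf.intercept_)
        pi1, pi2 = clf.priors_
        assert score[0] == pytest.approx(np.log(pi2 / pi1), abs=1e-10)


class TestPredict:
    def test_prior_dominance_all_negative(self):
        score = core.catch_score(np.zeros((4, 1, 1)), np.zeros((4, 0)),
                                 np.zeros((1, 1, 0)), np.zeros((1, 1)),
                                 np.zeros(0), np.log(0.25 / 0.75))
        assert np.all(core.predict_from_score(score) == 1)

    def test_one_sample_hand_computation(self):
        # d = 1x1, B = 1, M_adj = 0.5, gamma = 0, a2 = -0.2 -> score 0.3
        score = core.catch_score(np.array([[[0.5]]]), np.zeros((1, 0)),
                                 np.zeros((1, 1, 0)), np.array([[1.0]]),
                                 np.zeros(0), -0.2)
        assert score[0] == pytest.approx(0.3)
        assert core.predict_from_score(score)[0] == 2

    def test_tie_goes_to_mss(self):
        assert core.predict_from_score(np.array([0.0]))[0] == 1
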