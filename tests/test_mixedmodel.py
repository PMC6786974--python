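"""Kinship, matrix-normal EM, heritability, genetic correlation and the
multi-trait Wald test."""

import numpy as np
import pytest
from scipy import stats

import mtgwas as m
from mtgwas.errors import ParameterError
from mtgwas.mixedmodel import (CovarianceFit, KinshipMatrix,
                               matrix_normal_loglik)
from mtgwas.simdata import psd_sqrt

from conftest import sample_matrix_normal


class TestComputeRRM:
    def test_duplicated_samples_share_kinship_entries(self):
        G = m.simulate_genotypes(30, 200, seed=61)
        dos = G.dosages.copy()
        dos[1] = dos[0]  # make samples 0 and 1 genetically identical
        G2 = m.GenotypeSet(samples=G.samples, dosages=dos, variants=G.variants)
        K = m.compute_rrm(G2).values
        np.testing.assert_allclose(K[0, 1], K[0, 0], atol=1e-10)
        np.testing.assert_allclose(K[0, 0], K[1, 1], atol=1e-10)

    def test_matches_naive_double_loop_oracle(self):
        G = m.simulate_genotypes(50, 100, seed=62)
        K = m.compute_rrm(G).values
        X = G.dosages
        p = X.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        X, p = X[:, keep], p[keep]
        mm = X.shape[1]
        K_naive = np.zeros((50, 50))
        for i in range(50):
            for j in range(50):
                K_naive[i, j] = np.sum(
                    (X[i] - 2 * p) * (X[j] - 2 * p) / (2 * p * (1 - p))) / mm
        np.testing.assert_allclose(K, K_naive, atol=1e-10)

    def test_mean_diagonal_near_one(self):
        G = m.simulate_genotypes(200, 5000, seed=63, ld_decay=np.inf)
        K = m.compute_rrm(G).values
        assert 0.9 < np.diag(K).mean() < 1.1

    def test_loco_excludes_chromosome(self):
        G = m.simulate_genotypes(40, 100, seed=64, n_chromosomes=2)
        K_all = m.compute_rrm(G)
        K_loco = m.compute_rrm(G, loco_exclude="1")
        assert K_loco.loco_excluded_chrom == "1"
        assert not np.allclose(K_all.values, K_loco.values)
        # LOCO kinship must equal the RRM over chromosome-2 variants only
        keep = (G.variants["chrom"] == "2").to_numpy()
        K_manual = m.compute_rrm(G.subset_variants(keep))
        np.testing.assert_allclose(K_loco.values, K_manual.values, atol=1e-12)

    def test_everything_excluded_rejected(self):
        G = m.simulate_genotypes(10, 20, seed=65, n_chromosomes=1)
        with pytest.raises(ParameterError):
            m.compute_rrm(G, loco_exclude="1")


class TestMatrixNormalLikelihood:
    @pytest.mark.parametrize("n,p", [(8, 2), (20, 3), (12, 1)])
    def test_equals_brute_force_vec_normal_density(self, n, p):
        rng = np.random.default_rng(n * 10 + p)
        A = rng.standard_normal((n, n))
        K = A @ A.T / n + 0.3 * np.eye(n)
        B = np.cov(rng.standard_normal((p, 3 * p))) if p > 1 else np.array([[0.7]])
        E = np.eye(p) * 0.6 + 0.1
        KM = KinshipMatrix(values=(K + K.T) / 2, samples=[str(i) for i in range(n)])
        lam, Q = KM.eigendecomposition()
        Y = rng.standard_normal((n, p))
        ll = matrix_normal_loglik(Q.T @ Y, lam, np.atleast_2d(B), E)
        Sigma = np.kron(np.atleast_2d(B), KM.values) + np.kron(E, np.eye(n))
        ll_bf = stats.multivariate_normal.logpdf(Y.flatten(order="F"),
                                                 mean=np.zeros(n * p), cov=Sigma)
        assert abs(ll - ll_bf) < 1e-8


class TestFitMatrixNormal:
    def test_loglik_trace_non_decreasing(self, rrm_2000, kinship_sqrt_2000):
        B0 = np.array([[0.5, 0.25], [0.25, 0.5]])
        E0 = 0.5 * np.eye(2)
        rng = np.random.default_rng(70)
        Y = sample_matrix_normal(kinship_sqrt_2000, B0, E0, 2000, 2, rng)
        fit = m.fit_matrix_normal(Y, rrm_2000)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))
        assert fit.converged

    def test_estimates_are_psd(self, rrm_2000, kinship_sqrt_2000):
        rng = np.random.default_rng(71)
        Y = sample_matrix_normal(kinship_sqrt_2000, 0.4 * np.eye(3),
                                 0.6 * np.eye(3), 2000, 3, rng)
        fit = m.fit_matrix_normal(Y, rrm_2000)
        assert np.linalg.eigvalsh(fit.B).min() >= -1e-10
        assert np.linalg.eigvalsh(fit.E).min() >= -1e-10

    def test_single_trait_matches_grid_search_oracle(self, rrm_2000,
                                                     kinship_sqrt_2000):
        """EM heritability for one trait agrees with a brute-force profile
        maximum-likelihood grid over h2 in [0, 1] (step 0.001)."""
        n = 2000
        rng = np.random.default_rng(72)
        y = (np.sqrt(0.5) * (kinship_sqrt_2000 @ rng.standard_normal(n))
             + np.sqrt(0.5) * rng.standard_normal(n))
        # oracle: profile out the total variance on a fine h2 grid
        lam, Q = rrm_2000.eigendecomposition()
        yr = Q.T @ y
        grid = np.arange(0.0, 1.0001, 0.001)

        def profile_ll(h):
            v = h * lam + (1 - h)
            if v.min() <= 0:  # h = 1 with a rank-deficient kinship
                return -np.inf
            s2 = np.mean(yr * yr / v)
            return -0.5 * (np.log(v).sum() + n * np.log(s2) + n)

        h2_grid = grid[int(np.argmax([profile_ll(h) for h in grid]))]
        fit = m.fit_matrix_normal(y[:, None], rrm_2000, tol=1e-10,
                                  max_iter=20000)
        h2_em = fit.B[0, 0] / (fit.B[0, 0] + fit.E[0, 0])
        assert abs(h2_em - h2_grid) <= 0.005

    def test_missing_values_rejected(self, rrm_2000):
        Y = np.full((2000, 2), np.nan)
        with pytest.raises(ParameterError):
            m.fit_matrix_normal(Y, rrm_2000)

    def test_more_traits_than_samples_rejected(self):
        K = KinshipMatrix(values=np.eye(3), samples=["a", "b", "c"])
        with pytest.raises(ParameterError):
            m.fit_matrix_normal(np.zeros((3, 4)), K)


def manual_fit(B, E, lam=None, n=10):
    """CovarianceFit stub for formula-level tests."""
    B, E = np.atleast_2d(B), np.atleast_2d(E)
    lam = np.ones(n) if lam is None else lam
    return CovarianceFit(B=B, E=E, loglik_trace=[0.0], converged=True,
                         n_iter=1, eigenvalues=lam, eigenvectors=np.eye(n))


class TestHeritability:
    def test_formula(self):
        fit = manual_fit([[2.0]], [[2.0]])
        h2 = m.heritability(fit)
        assert h2.h2[0] == 0.5

    def test_zero_genetic_variance_not_significant(self):
        fit = manual_fit([[0.0]], [[1.0]])
        h2 = m.heritability(fit)
        assert h2.h2[0] == 0.0
        assert not h2.significant[0]

    def test_ci_covers_truth(self, rrm_2000, kinship_sqrt_2000):
        """95% CI for h2 = 0.6 covers the truth in >= 18 of 20 replicates."""
        n = 2000
        cover = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            y = (np.sqrt(0.6) * (kinship_sqrt_2000 @ rng.standard_normal(n))
                 + np.sqrt(0.4) * rng.standard_normal(n))
            fit = m.fit_matrix_normal(y[:, None], rrm_2000)
            row = m.heritability(fit).iloc[0]
            cover += (row.ci_low <= 0.6 <= row.ci_high)
        assert cover >= 18


class TestGeneticCorrelation:
    def test_formula(self):
        fit = manual_fit([[1.0, 0.5], [0.5, 1.0]], np.eye(2))
        assert m.genetic_correlation(fit, 0, 1) == 0.5

    def test_diagonal_B_gives_zero_correlation(self):
        fit = manual_fit(np.diag([1.0, 2.0]), np.eye(2))
        assert m.genetic_correlation(fit, 0, 1) == 0.0

    def test_zero_diagonal_rejected(self):
        fit = manual_fit(np.diag([0.0, 1.0]), np.eye(2))
        with pytest.raises(ParameterError):
            m.genetic_correlation(fit, 0, 1)

    def test_clipped_to_unit_interval(self):
        fit = manual_fit([[0.1, 0.2], [0.2, 0.1]], np.eye(2))
        assert m.genetic_correlation(fit, 0, 1) == 1.0


class TestMultiTraitTest:
    def test_orthogonal_dosage_gives_null_statistic(self, identity_kinship_200):
        rng = np.random.default_rng(80)
        Y = rng.standard_normal((200, 3))
        fit = m.fit_matrix_normal(Y, identity_kinship_200)
        # with K = I the rotation is orthogonal; build g orthogonal to Y
        q, _ = np.linalg.qr(np.column_stack([Y, np.ones(200)]))
        g = rng.standard_normal(200)
        g -= q @ (q.T @ g)
        alpha, chi2, nlp = m.multi_trait_test(Y, g, fit)
        assert chi2 < 1e-16
        np.testing.assert_allclose(alpha, 0.0, atol=1e-10)
        assert nlp < 1e-12

    def test_invariant_to_trait_order(self, identity_kinship_200):
        rng = np.random.default_rng(81)
        Y = rng.standard_normal((200, 4))
        g = rng.integers(0, 3, 200).astype(float)
        fit = m.fit_matrix_normal(Y, identity_kinship_200)
        _, chi2, _ = m.multi_trait_test(Y, g, fit)
        perm = [2, 0, 3, 1]
        fit_p = CovarianceFit(B=fit.B[np.ix_(perm, perm)],
                              E=fit.E[np.ix_(perm, perm)],
                              loglik_trace=[0.0], converged=True, n_iter=1,
                              eigenvalues=fit.eigenvalues,
                              eigenvectors=fit.eigenvectors)
        _, chi2_p, _ = m.multi_trait_test(Y[:, perm], g, fit_p)
        assert abs(chi2 - chi2_p) < 1e-8

    def test_matches_multivariate_ols_when_B_zero(self, identity_kinship_200):
        """With B = 0 the GLS collapses to multivariate OLS: chi-square equals
        (g'g) alpha_ols' E^-1 alpha_ols."""
        rng = np.random.default_rng(82)
        n, p = 200, 3
        Y = rng.standard_normal((n, p))
        g = rng.integers(0, 3, n).astype(float)
        E = np.cov(Y.T)
        fit = manual_fit(np.zeros((p, p)), E, lam=np.ones(n), n=n)
        alpha, chi2, _ = m.multi_trait_test(Y, g, fit)
        gc = g - g.mean()
        Yc = Y - Y.mean(axis=0)
        alpha_ols = Yc.T @ gc / (gc @ gc)
        np.testing.assert_allclose(alpha, alpha_ols, atol=1e-10)
        chi2_ols = (gc @ gc) * alpha_ols @ np.linalg.solve(E, alpha_ols)
        np.testing.assert_allclose(chi2, chi2_ols, atol=1e-8)

    def test_single_trait_agrees_with_mass_gwas_under_null(self):
        """At near-zero heritability the P = 1 multi-trait chi-square ranks
        variants like the simple-regression engine."""
        n = 500
        G = m.simulate_genotypes(n, 500, seed=83, ld_decay=np.inf)
        rng = np.random.default_rng(84)
        y = rng.standard_normal(n)
        K = m.compute_rrm(G)
        fit = m.fit_matrix_normal(y[:, None], K)
        _, chi2, _ = m.multi_trait_scan(y[:, None], G.dosages, fit)
        table = m.PhenotypeTable(samples=G.samples, values=y[:, None], names=["y"])
        res = m.run_mass_gwas(G, table).set_index("variant")
        t2 = res.loc[G.variants["id"], "t"].to_numpy() ** 2
        rho = stats.spearmanr(chi2, t2).statistic
        assert rho > 0.95
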