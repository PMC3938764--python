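import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture

from migranger.population import (cva, fit_mixture_em, hcluster_group_means,
                                  kde_gaussian, ks_two_sample,
                                  mahalanobis_pairwise, manova_wilks,
                                  n_components_for_variance, pca_svd,
                                  select_n_subpopulations)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 1))
        v = rng.normal(size=(1, 6))
        _, _, fractions = pca_svd(u @ v)
        assert fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(1)
        _, _, fractions = pca_svd(rng.normal(size=(100, 8)))
        assert fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(fractions) <= 1e-12)

    def test_scores_match_covariance_eigendecomposition(self):
        """Scores agree (up to sign) with the eigendecomposition-of-
        covariance route."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        scores, loadings, _ = pca_svd(X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        ref = Xc @ evecs[:, order]
        for j in range(5):
            s = np.sign(np.dot(scores[:, j], ref[:, j])) or 1.0
            assert scores[:, j] == pytest.approx(s * ref[:, j], abs=1e-8)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            pca_svd(np.ones((1, 3)))

    def test_component_count_for_variance_target(self):
        fractions = np.array([0.5, 0.3, 0.15, 0.05])
        assert n_components_for_variance(fractions, 0.85) == 3


class TestMixtureEm:
    def test_single_component_recovers_sample_moments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2.0, 1.5, size=(200, 2))
        fit = fit_mixture_em(X, 1, seed=0)
        assert fit.means[0] == pytest.approx(X.mean(axis=0), abs=1e-9)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 1, (300, 3)), rng.normal(5, 1, (300, 3))])
        fit = fit_mixture_em(X, 3, seed=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_well_separated_pair_high_label_accuracy(self):
        """Two Gaussians 10 sigma apart: label accuracy >= 99%."""
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 1, (400, 2)), rng.normal(10, 1, (400, 2))])
        truth = np.repeat([0, 1], 400)
        fit = fit_mixture_em(X, 2, seed=2)
        labels = fit.labels - 1
        acc = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert acc >= 0.99

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        fit = fit_mixture_em(rng.normal(size=(100, 2)), 3, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_aic_parameter_count(self):
        """AIC = 2k - 2 lnL with k = (K-1) + K d + K d(d+1)/2."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 3))
        fit = fit_mixture_em(X, 2, seed=0)
        k = (2 - 1) + 2 * 3 + 2 * 3 * 4 // 2
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood)

    def test_matches_sklearn_loglikelihood(self):
        """Independent EM route (sklearn) reaches the same optimum on an
        easy two-component problem."""
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(0, 1, (300, 2)), rng.normal(8, 1, (300, 2))])
        fit = fit_mixture_em(X, 2, seed=3)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(X)
        assert fit.log_likelihood == pytest.approx(gm.score(X) * len(X), rel=1e-4)

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture_em(np.random.default_rng(0).normal(size=(15, 2)), 2)


class TestModelSelection:
    def test_search_grid_is_2_to_8(self):
        rng = np.random.default_rng(9)
        X = np.concatenate([rng.normal(0, 1, (300, 2)), rng.normal(8, 1, (300, 2))])
        _, _, curve = select_n_subpopulations(X, restarts=2, final_restarts=1, seed=0)
        assert sorted(curve) == [2, 3, 4, 5, 6, 7, 8]

    def test_two_component_structure_detected(self):
        """On a well-separated two-component draw the AIC curve drops
        sharply from K=2 to the truth-capable models and never underfits;
        the K=2 assignment itself recovers the components essentially
        perfectly.  (AIC is known to overshoot the component count on
        Gaussian mixtures, so the selected K may exceed 2.)"""
        rng = np.random.default_rng(10)
        d = 3
        X = np.concatenate([rng.normal(0, 1, (600, d)),
                            rng.normal(np.r_[8, np.zeros(d - 1)], 1, (600, d))])
        best_k, fit, curve = select_n_subpopulations(X, restarts=5,
                                                     final_restarts=5, seed=1)
        assert best_k >= 2  # never underfits the true structure
        assert curve[2] < curve[8] + 2 * abs(curve[2]) * 0.01
        two = fit_mixture_em(X, 2, seed=0)
        truth = np.repeat([1, 2], 600)
        acc = max(np.mean(two.labels == truth), np.mean(two.labels == 3 - truth))
        assert acc >= 0.999


class TestRestartBatch:
    def test_batched_restart_lls_match_single_fits(self):
        """The batched restart evaluator reproduces the endpoint
        log-likelihood of each individually seeded EM fit."""
        from migranger.population import _batched_em_lls

        rng = np.random.default_rng(31)
        X = np.concatenate([rng.normal(0, 1, (200, 2)),
                            rng.normal(7, 1, (200, 2))])
        seeds = [5, 9, 13]
        lls, aics, spurious = _batched_em_lls(X, 2, seeds)
        for s, ll, aic in zip(seeds, lls, aics):
            ref = fit_mixture_em(X, 2, seed=s)
            assert ll == pytest.approx(ref.log_likelihood, abs=1e-6)
            assert aic == pytest.approx(ref.aic, abs=1e-6)


class TestCva:
    def test_cv1_matches_lda_direction(self):
        """Two groups separated along e1: CV1 aligns with the two-class LDA
        direction (|cos| > 0.99)."""
        rng = np.random.default_rng(11)
        X = np.concatenate([rng.normal(0, 1, (200, 4)),
                            rng.normal(np.r_[4, 0, 0, 0], 1, (200, 4))])
        labels = np.repeat([1, 2], 200)
        res = cva(X, labels)
        lda = LinearDiscriminantAnalysis().fit(X, labels)
        v1 = res["vectors"][:, 0]
        w = lda.coef_[0]
        cos = abs(v1 @ w) / (np.linalg.norm(v1) * np.linalg.norm(w))
        assert cos > 0.99

    def test_identical_groups_leading_eigenvalue_near_zero(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(400, 3))
        labels = np.repeat([1, 2], 200)
        res = cva(X, labels)
        assert res["eigenvalues"][0] < 0.05

    def test_between_fractions_ordered(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(300, 4))
        X[100:200, 0] += 3
        X[200:, 1] += 1.5
        labels = np.repeat([1, 2, 3], 100)
        res = cva(X, labels)
        fr = res["between_fractions"]
        assert fr[0] >= fr[-1]
        assert fr[0] == max(fr)


class TestMahalanobis:
    def test_identical_means_zero_distance(self):
        rng = np.random.default_rng(14)
        X = np.concatenate([rng.normal(size=(200, 3))] * 2)
        labels = np.repeat([1, 2], 200)
        D, groups, _ = mahalanobis_pairwise(X, labels)
        assert D[0, 1] < 0.5
        assert D[0, 0] == 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(15)
        n = 4000
        X = np.concatenate([rng.normal(0, 1, (n, 2)), rng.normal([3, 4], 1, (n, 2))])
        labels = np.repeat([1, 2], n)
        D, _, _ = mahalanobis_pairwise(X, labels)
        mu_diff = X[labels == 1].mean(0) - X[labels == 2].mean(0)
        assert D[0, 1] == pytest.approx(np.linalg.norm(mu_diff), rel=0.05)

    def test_three_group_toy_matches_hand_calculation(self):
        """Groups with hand-computable pooled covariance: D matches the
        explicit formula."""
        g1 = np.array([[0.0, 0], [2, 0], [0, 2], [2, 2]])
        g2 = g1 + [10, 0]
        g3 = g1 + [0, 10]
        X = np.concatenate([g1, g2, g3])
        labels = np.repeat([1, 2, 3], 4)
        D, groups, _ = mahalanobis_pairwise(X, labels)
        W = sum(((g - g.mean(0)).T @ (g - g.mean(0)) for g in (g1, g2, g3)))
        S = W / (12 - 3)
        Sinv = np.linalg.inv(S)
        for (a, b), (ga, gb) in {(0, 1): (g1, g2), (0, 2): (g1, g3),
                                 (1, 2): (g2, g3)}.items():
            diff = ga.mean(0) - gb.mean(0)
            assert D[a, b] == pytest.approx(np.sqrt(diff @ Sinv @ diff), abs=1e-9)
        assert D == pytest.approx(D.T)


class TestHierarchicalClustering:
    def test_two_groups_merge_at_their_distance(self):
        X = np.array([[0.0, 0], [0, 0.2], [5, 0], [5, 0.2]])
        labels = np.array([1, 1, 2, 2])
        Z, groups = hcluster_group_means(X, labels)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_collinear_means_merge_closest_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        labels = np.array([1, 2, 3])
        Z, groups = hcluster_group_means(X, labels)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 1}  # groups at 0 and 1

    def test_matches_scipy_single_linkage_oracle(self):
        rng = np.random.default_rng(16)
        means = rng.normal(size=(5, 3)) * 4
        X = np.concatenate([m + rng.normal(0, 0.01, (10, 3)) for m in means])
        labels = np.repeat(np.arange(1, 6), 10)
        Z, _ = hcluster_group_means(X, labels)
        group_means = np.stack([X[labels == g].mean(0) for g in range(1, 6)])
        ref = scipy_linkage(group_means, method="single")
        assert Z == pytest.approx(ref)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestManova:
    def test_identical_group_means_lambda_one(self):
        """Mirror-constructed groups share the exact mean: B = 0, Lambda = 1."""
        rng = np.random.default_rng(17)
        half = rng.normal(size=(100, 3))
        X = np.concatenate([half, -half, half, -half])
        labels = np.repeat([1, 2], 200)
        wilks, p = manova_wilks(X, labels)
        assert wilks == pytest.approx(1.0, abs=1e-12)
        assert p > 0.99

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(18)
        X = np.concatenate([rng.normal(0, 1, (100, 3)), rng.normal(2, 1, (100, 3))])
        labels = np.repeat([1, 2], 100)
        wilks, p = manova_wilks(X, labels)
        assert wilks < 0.5
        assert p < 1e-6

    def test_null_type_one_error_calibrated(self):
        """Random labels: p < 0.05 in 5% +/- 2% of replicates."""
        rng = np.random.default_rng(19)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            X = rng.normal(size=(60, 3))
            labels = rng.integers(1, 4, 60)
            _, p = manova_wilks(X, labels)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestKs:
    def test_identical_samples_zero_statistic(self):
        x = np.arange(50.0)
        D, _, reject = ks_two_sample(x, x)
        assert D == 0.0 and not reject

    def test_disjoint_supports_statistic_one(self):
        D, p, reject = ks_two_sample(np.arange(50.0), np.arange(100.0, 150.0))
        assert D == 1.0 and reject

    def test_critical_value_at_equal_n_100(self):
        """n = m = 100: critical D = 1.358 * sqrt(2/100) ~ 0.192."""
        rng = np.random.default_rng(20)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        crit = 1.358 * np.sqrt(2 / 100)
        assert crit == pytest.approx(0.192, abs=0.001)
        D, _, reject = ks_two_sample(x, y)
        assert reject == bool(D > crit)


class TestKde:
    def test_single_point_gaussian_bump(self):
        f = kde_gaussian(np.array([2.0]), bandwidth=0.5)
        grid = np.linspace(-3, 7, 2001)
        vals = f(grid)
        assert grid[np.argmax(vals)] == pytest.approx(2.0, abs=0.01)
        assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-6)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(21)
        f = kde_gaussian(rng.normal(size=300), bandwidth=0.4)
        grid = np.linspace(-8, 8, 4001)
        assert np.trapezoid(f(grid), grid) == pytest.approx(1.0, abs=1e-6)

    def test_large_sample_consistency(self):
        """KDE of a large Gaussian sample tracks the true pdf within 0.02."""
        rng = np.random.default_rng(22)
        x = rng.normal(size=20000)
        f = kde_gaussian(x, bandwidth=0.25)
        grid = np.linspace(-4, 4, 801)
        true = np.exp(-0.5 * grid ** 2) / np.sqrt(2 * np.pi)
        assert np.max(np.abs(f(grid) - true)) < 0.02

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_gaussian(np.arange(5.0), 0.0)
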