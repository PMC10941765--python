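import numpy as np
import pandas as pd
import pytest
from itertools import permutations as iter_permutations
from scipy import stats as sps

from ndoikit import MonthlyCaseTable, pca, permutation_test, rare_filter, rda, variable_ranking
from ndoikit.ordination import RDA, OrdinationError

TOY_Y = np.array([[5, 3, 2], [1, 4, 7], [6, 6, 1], [2, 8, 3], [9, 2, 5], [4, 5, 6]], float)
TOY_X = np.array([[1, 2], [2, 1.5], [3, 4], [4, 2.5], [5, 5], [6, 3]], float)


class TestRareFilter:
    def _table(self, freq_nonzero: dict, n_months=48):
        from ndoikit import DiseaseCatalog
        cols = {}
        for name, k in freq_nonzero.items():
            col = np.zeros(n_months, dtype=int)
            col[:k] = 1
            cols[name] = col
        catalog = DiseaseCatalog([(d, "airborne") for d in freq_nonzero])
        months = pd.period_range("2017-01", periods=n_months, freq="M")
        return MonthlyCaseTable(pd.DataFrame(cols, index=months), catalog)

    def test_five_percent_threshold_boundaries(self):
        t = self._table({"never": 0, "twice": 2, "thrice": 3, "common": 48})
        kept = rare_filter(t, 0.05)
        # 2/48 = 4.17% < 5% removed; 3/48 = 6.25% kept
        assert kept.diseases == ("thrice", "common")

    def test_zero_threshold_is_identity(self):
        t = self._table({"never": 0, "common": 48})
        assert rare_filter(t, 0.0).diseases == t.diseases

    def test_all_removed_errors(self):
        t = self._table({"never": 0, "once": 1})
        with pytest.raises(OrdinationError, match="every disease"):
            rare_filter(t, 0.5)


class TestPCA:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0, 0], [1, 2], [2, 4], [3, 6.0]])
        res = pca(pts)
        assert len(res.eigenvalues) == 1
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_standardized_trace_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        res = pca(X, standardize=True)
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert res.explained_fraction.sum() == pytest.approx(1.0)

    def test_matches_brute_force_eigendecomposition(self):
        X = np.array([[1, 2], [3, 5], [4, 4], [7, 9.0]])
        res = pca(X)
        C = np.cov((X - X.mean(0)).T)
        brute = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert res.eigenvalues == pytest.approx(brute, abs=1e-10)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 4))
        assert pca(X).eigenvalues == pytest.approx(
            SkPCA().fit(X).explained_variance_, abs=1e-10)

    def test_zero_variance_column_with_standardize(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(OrdinationError, match="'b'"):
            pca(X, standardize=True)

    def test_site_scores_reconstruct_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        res = pca(X)
        Xc = X - X.mean(0)
        loadings = res.species_scores.to_numpy() / np.sqrt(res.eigenvalues)
        assert np.allclose(res.site_scores.to_numpy() @ loadings.T, Xc, atol=1e-8)


class TestRDA:
    def test_matches_two_step_brute_force_oracle(self):
        # independent oracle: multivariate least squares, then
        # eigendecomposition of the fitted-value covariance
        res = rda(TOY_Y, TOY_X)
        Ys = (TOY_Y - TOY_Y.mean(0)) / TOY_Y.std(0, ddof=1)
        Xs = (TOY_X - TOY_X.mean(0)) / TOY_X.std(0, ddof=1)
        B = np.linalg.pinv(Xs) @ Ys
        fitted = Xs @ B
        brute = np.sort(np.linalg.eigvalsh(np.cov(fitted.T)))[::-1][:2]
        assert res.eigenvalues == pytest.approx(brute, abs=1e-10)

    def test_matches_vegan_frozen_values(self):
        # frozen from R vegan 2.7: rda(scale(Y) ~ X1 + X2) on the same toy
        res = rda(TOY_Y, TOY_X)
        assert res.eigenvalues == pytest.approx([1.144114563856, 0.229925096396], abs=1e-9)
        assert res.total_variance == pytest.approx(3.0, abs=1e-12)
        assert res.constrained_fraction == pytest.approx(0.458013220084, abs=1e-9)

    def test_orthogonal_env_explains_nothing(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 3))
        # build env exactly orthogonal to every centered species column
        Yc = Y - Y.mean(0)
        q, _ = np.linalg.qr(np.hstack([Yc, rng.normal(size=(8, 1))]))
        env = q[:, [3]]  # orthogonal to the span of Yc
        res = rda(Y, env, scale_species=False)
        assert res.constrained_fraction == pytest.approx(0.0, abs=1e-10)

    def test_perfect_linear_map_fully_explained(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        Y = X @ np.array([[1.0, -2, 0.5], [0.3, 1, 2]])
        res = rda(Y, X)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_env_reduces_to_pca(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(7, 3))
        env = rng.normal(size=(7, 6))  # spans the 6-dim site space
        res = rda(Y, env, scale_species=False)
        ref = pca(Y)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-8)
        assert res.eigenvalues == pytest.approx(ref.eigenvalues, abs=1e-8)

    def test_variance_partition(self):
        res = rda(TOY_Y, TOY_X)
        total = res.eigenvalues.sum() + res.residual_eigenvalues.sum()
        assert total == pytest.approx(res.total_variance, abs=1e-8)

    def test_collinear_covariate_dropped(self):
        E = pd.DataFrame({"a": TOY_X[:, 0], "b": TOY_X[:, 1], "a2": 2 * TOY_X[:, 0] + 1})
        with pytest.warns(UserWarning, match="a2"):
            model = RDA().fit(E, TOY_Y)
        assert model.env_columns_ == ("a", "b")

    def test_too_many_covariates_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(OrdinationError, match="covariates"):
            rda(rng.normal(size=(4, 2)), rng.normal(size=(4, 5)))

    def test_deterministic_axis_signs(self):
        res1, res2 = rda(TOY_Y, TOY_X), rda(TOY_Y, TOY_X)
        pd.testing.assert_frame_equal(res1.species_scores, res2.species_scores)
        for k in range(res1.species_scores.shape[1]):
            col = res1.species_scores.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0


class TestPermutationTest:
    def test_constant_species_p_one(self):
        Y = np.ones((6, 2))
        assert permutation_test(Y, TOY_X, permutations=49, seed=0) == 1.0

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 1))
        Y = X @ np.array([[1.0, 2.0]]) + rng.normal(size=(12, 2)) * 1e-6
        assert permutation_test(Y, X, permutations=499, seed=0) == pytest.approx(1 / 500)

    def test_monte_carlo_close_to_exhaustive_on_four_sites(self):
        Y = np.array([[1, 0.5], [2, 1.8], [3, 2.9], [5, 4.2]])
        X = np.array([[1.0], [2.1], [2.9], [4.5]])
        Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)

        def frac(Z):
            fitted = Z @ np.linalg.pinv(Z) @ Ys
            return (fitted ** 2).sum() / (Ys ** 2).sum()

        obs = frac(Xs)
        exact_ge = sum(frac(Xs[list(perm)]) >= obs - 1e-12
                       for perm in iter_permutations(range(4)))
        exact_p = exact_ge / 24   # identity is among the 24 orders
        mc = permutation_test(Y, X, permutations=499, seed=3)
        se = np.sqrt(exact_p * (1 - exact_p) / 499)
        assert abs(mc - exact_p) < max(4 * se, 0.05)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(6)
        Y, X = rng.normal(size=(10, 3)), rng.normal(size=(10, 2))
        p1 = permutation_test(Y, X, permutations=99, seed=42)
        p2 = permutation_test(Y, X, permutations=99, seed=42)
        assert p1 == p2

    def test_p_uniform_under_null(self):
        # association-free data: the p distribution over replicates must be
        # close to uniform
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            Y = rng.normal(size=(12, 3))
            X = rng.normal(size=(12, 1))
            pvals.append(permutation_test(Y, X, permutations=99, seed=rep))
        stat = sps.kstest(pvals, "uniform").statistic
        assert stat < 0.12, f"KS distance from uniform {stat:.3f}"


class TestVariableRanking:
    def test_single_covariate(self):
        ranking, _ = variable_ranking(TOY_Y, TOY_X[:, [0]])
        assert len(ranking) == 1
        assert ranking.iloc[0] == pytest.approx(
            rda(TOY_Y, TOY_X[:, [0]]).constrained_fraction)

    def test_duplicate_covariate_changes_nothing(self):
        E = pd.DataFrame({"a": TOY_X[:, 0], "b": TOY_X[:, 1]})
        E2 = E.assign(a_dup=E["a"])
        with pytest.warns(UserWarning):
            ranking2, joint2 = variable_ranking(TOY_Y, E2, subset=["a", "b"])
        ranking, joint = variable_ranking(TOY_Y, E, subset=["a", "b"])
        assert joint2 == pytest.approx(joint, abs=1e-12)
        pd.testing.assert_series_equal(ranking, ranking2)

    def test_planted_driver_ranked_first(self, planted_driver_sweep):
        share = planted_driver_sweep["n_top_ranked"] / planted_driver_sweep["n_seeds"]
        assert share >= 0.95
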