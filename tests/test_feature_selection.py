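"""Univariate F scores, kNN mutual information, and the Lasso path."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.feature_selection import mutual_info_regression
from sklearn.linear_model import LinearRegression

import pigsnp as pg
from pigsnp.feature_selection import (
    ALPHA_GRID,
    build_top_snp_list,
    compute_feature_scores,
    lasso_objective,
)


class TestUnivariateF:
    def test_hand_computed_five_point_example(self):
        """r=6/sqrt(40), F=r^2/(1-r^2)*(n-2)=27, p from F(1,3)."""
        X = np.array([[0], [0], [1], [2], [2]], dtype=float)
        y = np.array([0, 1, 2, 3, 4], dtype=float)
        table = pg.univariate_f_scores(X, y, ["snp"])
        assert table.loc["snp", "pearson_r"] == pytest.approx(6 / np.sqrt(40))
        assert table.loc["snp", "f_score"] == pytest.approx(27.0)
        assert table.loc["snp", "p_value"] == pytest.approx(
            stats.f.sf(27.0, 1, 3)
        )
        assert table.loc["snp", "p_value"] == pytest.approx(0.0138, abs=5e-4)

    def test_f_equals_squared_t_of_regression_slope(self, rng):
        """The univariate F statistic equals t^2 from the slope t-test."""
        for _ in range(20):
            n = int(rng.integers(10, 60))
            x = rng.binomial(2, 0.4, n).astype(float)
            if x.std() == 0:
                continue
            y = 0.3 * x + rng.normal(size=n)
            table = pg.univariate_f_scores(x[:, None], y, ["s"])
            lr = stats.linregress(x, y)
            t_stat = lr.slope / lr.stderr
            assert table.loc["s", "f_score"] == pytest.approx(t_stat**2, rel=1e-9)
            assert table.loc["s", "p_value"] == pytest.approx(lr.pvalue, rel=1e-9)

    def test_null_p_values_uniform(self, rng):
        """Independent target: ~1% of SNPs pass p < 0.01."""
        X = rng.binomial(2, 0.5, size=(100, 3000)).astype(float)
        y = rng.normal(size=100)
        table = pg.univariate_f_scores(X, y, [f"s{i}" for i in range(3000)])
        frac = (table["p_value"] < 0.01).mean()
        assert 0.003 < frac < 0.02

    def test_constant_snp_excluded(self):
        X = np.column_stack([np.ones(5), [0, 1, 0, 2, 1]]).astype(float)
        y = np.arange(5, dtype=float)
        table = pg.univariate_f_scores(X, y, ["const", "var"])
        assert np.isnan(table.loc["const", "f_score"])
        assert np.isfinite(table.loc["var", "f_score"])


class TestSelectByF:
    def test_p_gate_precedes_ranking(self):
        table = pd.DataFrame(
            {"f_score": [10.0, 50.0], "p_value": [0.005, 0.02]},
            index=pd.Index(["a", "b"], name="snp_id"),
        )
        assert pg.select_by_f(table) == ["a"]

    def test_empty_table_gives_empty_list(self):
        table = pd.DataFrame({"f_score": [], "p_value": []},
                             index=pd.Index([], name="snp_id"))
        assert pg.select_by_f(table) == []

    def test_equal_f_breaks_ties_lexicographically(self):
        table = pd.DataFrame(
            {"f_score": [5.0, 5.0, 7.0], "p_value": [0.001] * 3},
            index=pd.Index(["b", "a", "c"], name="snp_id"),
        )
        assert pg.select_by_f(table) == ["c", "a", "b"]


class TestMutualInfo:
    def test_independent_variables_near_zero(self, rng):
        x = rng.integers(0, 3, 2000).astype(float)
        y = rng.normal(size=2000)
        assert pg.mutual_info_scores(x[:, None], y, seed=0)[0] < 0.05

    def test_bivariate_gaussian_closed_form(self, rng):
        """MI of a rho=0.8 Gaussian pair is -ln(1-rho^2)/2 = 0.511 nats."""
        xy = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=2000)
        mi = pg.mutual_info_scores(xy[:, [0]], xy[:, 1], seed=0)[0]
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.64), abs=0.1)

    def test_deterministic_dependence_is_maximal(self, rng):
        X = rng.integers(0, 3, size=(500, 10)).astype(float)
        y = X[:, 0].copy()
        mi = pg.mutual_info_scores(X, y, seed=0)
        assert mi[0] == max(mi)
        # close to the entropy of a roughly uniform 3-level variable
        assert mi[0] > 0.8

    def test_permutation_invariance_in_samples(self, rng):
        x = rng.integers(0, 3, 400).astype(float)
        y = 0.5 * x + rng.normal(size=400)
        perm = rng.permutation(400)
        a = pg.mutual_info_scores(x[:, None], y, seed=0)[0]
        b = pg.mutual_info_scores(x[perm, None], y[perm], seed=0)[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_non_negative_over_random_inputs(self, rng):
        X = rng.integers(0, 3, size=(60, 50)).astype(float)
        y = rng.normal(size=60)
        assert (pg.mutual_info_scores(X, y, seed=1) >= 0).all()

    def test_matches_sklearn_mixed_estimator(self, rng):
        """Cross-check against sklearn's discrete/continuous kNN estimator.

        Tiny tolerance absorbs 1-ulp distance differences that can flip one
        neighbor count at tied distances.
        """
        X = rng.integers(0, 4, size=(300, 20)).astype(float)
        y = 0.4 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(size=300)
        mine = pg.mutual_info_scores(X, y, seed=0)
        theirs = mutual_info_regression(
            X, y, discrete_features=True, n_neighbors=3, random_state=0
        )
        assert np.allclose(mine, theirs, atol=0.05)
        assert np.corrcoef(mine, theirs)[0, 1] > 0.98

    def test_k_at_least_n_rejected(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            pg.mutual_info_scores(np.zeros((5, 1)), np.zeros(5), k_neighbors=5)


class TestLassoFit:
    def test_kkt_null_model_above_alpha_max(self, rng):
        X = rng.binomial(2, 0.5, (60, 15)).astype(float)
        y = rng.normal(2.0, 1.0, 60)
        alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / 60
        assert not pg.lasso_fit(X, y, alpha_max * 1.0001).nonzero().any()
        assert pg.lasso_fit(X, y, alpha_max * 0.9).nonzero().any()

    def test_soft_thresholding_on_orthonormal_design(self, rng):
        """With X^T X = I the solution is coordinatewise soft thresholding."""
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        b = Q.T @ (y - y.mean())
        alpha = 0.05
        expected = np.sign(b) * np.maximum(np.abs(b) - n * alpha, 0.0)
        spec = pg.lasso_fit(Q, y, alpha, tol=1e-12)
        assert np.allclose(spec.coef, expected, atol=1e-6)

    def test_alpha_zero_is_ordinary_least_squares(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        spec = pg.lasso_fit(X, y, 0.0)
        ols = LinearRegression().fit(X, y)
        assert np.allclose(spec.coef, ols.coef_)
        assert spec.intercept == pytest.approx(ols.intercept_)

    def test_matches_brute_force_grid_on_two_features(self, rng):
        """2-feature problem: compare against an exhaustive coefficient grid."""
        X = rng.normal(size=(50, 2))
        y = 0.8 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(scale=0.5, size=50)
        alpha = 0.1
        spec = pg.lasso_fit(X, y, alpha, tol=1e-12)
        grid = np.linspace(-1.5, 1.5, 601)  # step 0.005
        best, best_obj = None, np.inf
        for w0 in grid:
            resid0 = y - w0 * X[:, 0]
            for w1 in grid:
                w = np.array([w0, w1])
                intercept = (resid0 - w1 * X[:, 1]).mean()
                obj = lasso_objective(X, y, w, intercept, alpha)
                if obj < best_obj:
                    best, best_obj = w, obj
        assert np.allclose(spec.coef, best, atol=5e-3)
        assert spec.objective <= best_obj + 1e-9

    def test_objective_not_worse_than_zero_or_ols(self, rng):
        for trial in range(5):
            r = np.random.default_rng(trial)
            X = r.normal(size=(30, 6))
            y = r.normal(size=30)
            alpha = float(r.uniform(0.01, 0.5))
            spec = pg.lasso_fit(X, y, alpha, tol=1e-10)
            zero_obj = lasso_objective(X, y, np.zeros(6), y.mean(), alpha)
            ols = LinearRegression().fit(X, y)
            ols_obj = lasso_objective(X, y, ols.coef_, ols.intercept_, alpha)
            assert spec.objective <= zero_obj + 1e-9
            assert spec.objective <= ols_obj + 1e-9


class TestLassoPath:
    def test_nonzero_counts_non_increasing_in_alpha(self, rng):
        X = rng.binomial(2, 0.4, (80, 40)).astype(float)
        y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(size=80)
        path = pg.lasso_path(X, y, [f"s{i}" for i in range(40)])
        by_desc_alpha = [path.nonzero_counts[a]
                         for a in sorted(ALPHA_GRID, reverse=True)]
        assert all(a <= b for a, b in zip(by_desc_alpha, by_desc_alpha[1:]))

    def test_single_alpha_grid_equals_lasso_fit(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        path = pg.lasso_path(X, y, list("abcde"), alphas=(0.1,))
        spec = pg.lasso_fit(X, y, 0.1)
        assert np.allclose(path.coef(0.1).to_numpy(), spec.coef, atol=1e-8)

    def test_warm_start_agrees_with_cold_start(self, rng):
        X = rng.binomial(2, 0.4, (60, 25)).astype(float)
        y = X[:, 3] + rng.normal(size=60)
        path = pg.lasso_path(X, y, [f"s{i}" for i in range(25)], tol=1e-10)
        for alpha in (0.2, 0.05, 0.005):
            cold = pg.lasso_fit(X, y, alpha, tol=1e-10)
            assert np.allclose(path.coef(alpha).to_numpy(), cold.coef, atol=1e-5)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            pg.lasso_path(np.zeros((3, 1)), np.zeros(3), ["s"], alphas=())


class TestTopSnpList:
    def _scores(self, rng, n=60, p=40):
        X = rng.binomial(2, 0.5, (n, p)).astype(float)
        y = X[:, 0] - X[:, 1] + rng.normal(size=n)
        ids = [f"s{i:02d}" for i in range(p)]
        return compute_feature_scores(X, y, ids, seed=0), X, y, ids

    def test_union_reproduced_by_brute_force(self, rng):
        """Flags recomputed independently from the raw score table."""
        scores, X, y, ids = self._scores(rng)
        top = build_top_snp_list(scores, "pooled", top_k=10)
        tab = scores.table
        gated = tab[tab["p_value"] < 0.01]
        exp_f = set(gated.sort_values(["f_score", "snp_id"],
                                      ascending=[False, True]).head(10).index)
        exp_mi = set(tab.sort_values(["mi", "snp_id"],
                                     ascending=[False, True]).head(10).index)
        exp_lasso = {
            a: {s for s in ids if abs(scores.path.coef(a)[s]) > 1e-8}
            for a in (0.5, 0.2, 0.1, 0.01, 0.005)
        }
        expected_union = exp_f | exp_mi | set().union(*exp_lasso.values())
        assert set(top.snp_ids) == expected_union
        assert set(top.flags.index[top.flags["top_f"]]) == exp_f
        assert set(top.flags.index[top.flags["top_mi"]]) == exp_mi
        for a, ids_a in exp_lasso.items():
            assert set(top.flags.index[top.flags[f"nonzero_a{a:g}"]]) == ids_a

    def test_snp_in_several_routes_appears_once(self, rng):
        scores, *_ = self._scores(rng)
        top = build_top_snp_list(scores, "pooled")
        assert len(top.snp_ids) == len(set(top.snp_ids))

    def test_all_zero_lasso_reduces_to_f_mi_union(self, rng):
        X = rng.binomial(2, 0.5, (50, 20)).astype(float)
        y = rng.normal(size=50) * 0.01  # tiny target: large alphas kill all
        ids = [f"s{i}" for i in range(20)]
        scores = compute_feature_scores(X, y, ids, seed=0)
        top = build_top_snp_list(scores, "pooled", top_k=5,
                                 lasso_alphas=(0.7, 0.5))
        expected = set(scores.top_ids("f", 5)) | set(scores.top_ids("mi", 5))
        assert set(top.snp_ids) == expected
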