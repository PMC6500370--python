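"""Regression engine: design building, the three models, and their nesting."""

import numpy as np
import pandas as pd
import pytest

from methylpred.io import ExpressionMatrix, MethylationMatrix, PairedDataset
from methylpred.regression import (
    GeneDesign,
    GeneSkipped,
    build_design,
    fit_lasso,
    fit_multiple,
    fit_single_best,
    pearson_r2,
)


def _paired(X, y, missing=None):
    """Wrap a (n x p) design and response into a PairedDataset for one gene."""
    n, p = X.shape
    samples = [f"S{i:03d}" for i in range(n)]
    probes = [f"cg{j:03d}" for j in range(p)]
    meth = pd.DataFrame(X.T.copy(), index=probes, columns=samples)
    if missing:
        for probe_j, sample_i in missing:
            meth.iloc[probe_j, sample_i] = np.nan
    expr = pd.DataFrame([y], index=["GENE"], columns=samples)
    return (
        PairedDataset(
            ExpressionMatrix(expr), MethylationMatrix(meth, scale="m"), samples
        ),
        probes,
    )


class TestBuildDesign:
    def test_listwise_deletion_counts(self, rng):
        X = rng.normal(size=(100, 1))
        y = rng.normal(size=100)
        paired, probes = _paired(X, y, missing=[(0, 1), (0, 5), (0, 7)])
        d = build_design("GENE", paired, probes)
        assert d.n_complete == 97

    def test_no_missing_keeps_all_samples(self, rng):
        X = rng.normal(size=(50, 2))
        paired, probes = _paired(X, rng.normal(size=50))
        assert build_design("GENE", paired, probes).n_complete == 50

    def test_disjoint_missingness_unions(self, rng):
        X = rng.normal(size=(100, 2))
        missing = [(0, i) for i in range(5)] + [(1, i) for i in range(5, 10)]
        paired, probes = _paired(X, rng.normal(size=100), missing=missing)
        assert build_design("GENE", paired, probes).n_complete == 90

    def test_too_few_complete_samples_skips(self, rng):
        X = rng.normal(size=(12, 1))
        missing = [(0, i) for i in range(4)]
        paired, probes = _paired(X, rng.normal(size=12), missing=missing)
        with pytest.raises(GeneSkipped, match="complete samples"):
            build_design("GENE", paired, probes)

    def test_constant_response_skips(self, rng):
        X = rng.normal(size=(30, 1))
        paired, probes = _paired(X, np.ones(30))
        with pytest.raises(GeneSkipped, match="constant expression"):
            build_design("GENE", paired, probes)

    def test_constant_probe_dropped(self, rng):
        X = rng.normal(size=(30, 2))
        X[:, 1] = 3.14
        paired, probes = _paired(X, rng.normal(size=30))
        d = build_design("GENE", paired, probes)
        assert d.probe_ids == ["cg000"]


class TestSingleRegression:
    def test_exact_linear_probe_selected_with_r2_one(self, rng):
        X = rng.normal(size=(40, 3))
        y = 2.0 * X[:, 1] + 1.0
        fit = fit_single_best(GeneDesign("g", X, y, ["a", "b", "c"]))
        assert fit.best_probe == "b"
        assert fit.best_r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_squared_correlation(self):
        # r = 6.5 / sqrt(5 * 8.75), so R² = 42.25 / 43.75
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        fit = fit_single_best(GeneDesign("g", X, y, ["a"]))
        assert fit.best_r2 == pytest.approx(42.25 / 43.75, abs=1e-12)

    def test_tie_broken_by_probe_order(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x.copy()])
        fit = fit_single_best(GeneDesign("g", X, rng.normal(size=30), ["a", "b"]))
        assert fit.best_probe == "a"

    def test_p_value_matches_scipy_linregress(self, rng):
        from scipy.stats import linregress

        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        fit = fit_single_best(GeneDesign("g", x[:, None], y, ["a"]))
        ref = linregress(x, y)
        assert fit.p_values[0] == pytest.approx(ref.pvalue, rel=1e-9)
        assert fit.best_r2 == pytest.approx(ref.rvalue**2, rel=1e-12)


class TestMultipleRegression:
    def test_single_probe_equals_single_regression(self, rng):
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + rng.normal(size=30)
        d = GeneDesign("g", X, y, ["a"])
        assert fit_multiple(d).fitting_r2 == pytest.approx(
            fit_single_best(d).best_r2, abs=1e-12
        )

    def test_saturated_design_interpolates_and_flags(self, rng):
        X = rng.normal(size=(8, 10))
        y = rng.normal(size=8)
        fit = fit_multiple(GeneDesign("g", X, y, [f"p{i}" for i in range(10)]))
        assert fit.fitting_r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.rank_deficient
        assert np.isnan(fit.overall_p)

    def test_orthogonal_predictors_add_their_marginal_r2(self):
        # 6-sample design with exactly orthogonal centered predictors whose
        # marginal shares of var(y) are 0.2 and 0.3; the normal equations
        # solved directly give joint R² = 0.5 (oracle below re-derives it)
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        x2 = x2 - x2.mean()
        x2 = x2 - x1 * (x1 @ x2) / (x1 @ x1)  # exact orthogonalization
        e = np.array([1.0, -1.0, -1.0, 1.0, 0.0, 0.0])
        e = e - e.mean()
        e -= x1 * (x1 @ e) / (x1 @ x1) + x2 * (x2 @ e) / (x2 @ x2)
        b1 = np.sqrt(0.2 / (x1 @ x1))
        b2 = np.sqrt(0.3 / (x2 @ x2))
        y = b1 * x1 + b2 * x2 + np.sqrt(0.5 / (e @ e)) * e
        X = np.column_stack([x1, x2])
        # oracle: explicit normal-equations solve
        A = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        oracle_r2 = pearson_r2(A @ beta, y)
        fit = fit_multiple(GeneDesign("g", X, y, ["a", "b"]))
        assert oracle_r2 == pytest.approx(0.5, abs=1e-12)
        d1 = fit_single_best(GeneDesign("g", X[:, :1], y, ["a"]))
        d2 = fit_single_best(GeneDesign("g", X[:, 1:], y, ["b"]))
        assert d1.best_r2 == pytest.approx(0.2, abs=1e-12)
        assert d2.best_r2 == pytest.approx(0.3, abs=1e-12)
        assert fit.fitting_r2 == pytest.approx(oracle_r2, abs=1e-12)

    def test_f_test_matches_statsmodels_style_formula(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ np.array([0.5, 0.0, -0.3]) + rng.normal(size=50)
        fit = fit_multiple(GeneDesign("g", X, y, list("abc")))
        from scipy import stats

        r2 = fit.fitting_r2
        f = (r2 / 3) / ((1 - r2) / (50 - 4))
        assert fit.overall_p == pytest.approx(float(stats.f.sf(f, 3, 46)), rel=1e-9)


class TestLasso:
    def test_path_matches_sklearn_lasso_path(self, rng):
        from sklearn.linear_model import lasso_path

        from methylpred._lasso import lasso_penalty_path, solve_lasso_path

        X = rng.normal(size=(60, 15))
        y = X[:, :3] @ np.array([1.0, -0.5, 0.8]) + rng.normal(size=60) * 1.5
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        alphas = lasso_penalty_path(Xs, ys)
        mine = solve_lasso_path(Xs, ys, alphas, tol=1e-10)
        _, ref, _ = lasso_path(Xs, ys, alphas=alphas, tol=1e-12, max_iter=10**6)
        assert np.max(np.abs(mine.T - ref)) < 1e-6

    def test_cv_selection_matches_sklearn_on_shared_folds(self, rng):
        from sklearn.linear_model import LassoCV
        from sklearn.model_selection import KFold

        from methylpred._lasso import lasso_cv_select, lasso_penalty_path

        X = rng.normal(size=(80, 10))
        y = X[:, 0] - 0.7 * X[:, 4] + rng.normal(size=80) * 1.2
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        alphas = lasso_penalty_path(Xs, ys)
        kf = KFold(10, shuffle=True, random_state=5)
        folds = [test for _, test in kf.split(Xs)]
        best, path, _ = lasso_cv_select(Xs, ys, alphas, folds)
        ref = LassoCV(alphas=alphas, cv=kf, tol=1e-8).fit(Xs, ys)
        assert alphas[best] == pytest.approx(ref.alpha_, rel=1e-12)
        assert np.max(np.abs(path[best] - ref.coef_)) < 1e-5

    def test_planted_support_recovered_across_seeds(self):
        # y = 2 x3 + small noise: probe 3 must enter with positive sign
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(200, 10))
            y = 2.0 * X[:, 3] + rng.normal(size=200) * 0.1
            fit = fit_lasso(
                GeneDesign("g", X, y, [f"p{j}" for j in range(10)]), seed=s
            )
            if fit.valid and fit.coefficients[3] > 0:
                hits += 1
        assert hits >= 95

    def test_pure_noise_often_yields_invalid_model(self):
        """With p >> n and no signal, minimum-CV-MSE penalty selection keeps
        the all-zero model in a large fraction of replicates — the same rate
        sklearn's LassoCV shows on identical data."""
        invalid = 0
        n_rep = 12
        for s in range(n_rep):
            rng = np.random.default_rng(5000 + s)
            X = rng.normal(size=(100, 200))
            y = rng.normal(size=100)
            fit = fit_lasso(
                GeneDesign("g", X, y, [f"p{j}" for j in range(200)]), seed=s
            )
            invalid += not fit.valid
        assert invalid >= n_rep // 3

    def test_constant_response_skipped(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(GeneSkipped):
            fit_lasso(GeneDesign("g", X, np.ones(30), list("abc")), seed=0)

    def test_seed_reproducible_and_path_seed_invariant(self, rng):
        X = rng.normal(size=(60, 8))
        y = X[:, 0] + rng.normal(size=60)
        d = GeneDesign("g", X, y, [f"p{j}" for j in range(8)])
        a = fit_lasso(d, seed=3)
        b = fit_lasso(d, seed=3)
        c = fit_lasso(d, seed=4)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.alpha_selected == b.alpha_selected
        np.testing.assert_allclose(a.alphas, c.alphas)  # path ignores the seed

    def test_coefficients_on_original_scale(self, rng):
        X = rng.normal(size=(100, 4)) * np.array([1.0, 10.0, 0.1, 1.0])
        y = 3.0 * X[:, 1] + rng.normal(size=100) * 0.5
        fit = fit_lasso(GeneDesign("g", X, y, list("abcd")), seed=0)
        pred = X @ fit.coefficients + fit.intercept
        assert pearson_r2(pred, y) == pytest.approx(fit.fitting_r2)
        assert fit.coefficients[1] == pytest.approx(3.0, rel=0.05)


class TestNestingInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_model_hierarchy_on_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(25, 50))
        p = int(rng.integers(2, 8))
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) * 0.3 + rng.normal(size=n)
        d = GeneDesign("g", X, y, [f"p{j}" for j in range(p)])
        single = fit_single_best(d).best_r2
        multiple = fit_multiple(d).fitting_r2
        lasso = fit_lasso(d, seed=seed).fitting_r2
        assert multiple >= single - 1e-10
        if np.isfinite(lasso):
            assert multiple >= lasso - 1e-8
        for v in (single, multiple):
            assert 0.0 <= v <= 1.0

    def test_all_probes_fit_at_least_subset_fit(self, rng):
        X = rng.normal(size=(60, 6))
        y = X @ np.array([0.5, -0.4, 0.0, 0.3, 0.0, 0.2]) + rng.normal(size=60)
        full = fit_multiple(GeneDesign("g", X, y, [f"p{j}" for j in range(6)]))
        sub = fit_multiple(GeneDesign("g", X[:, :3], y, [f"p{j}" for j in range(3)]))
        assert full.fitting_r2 >= sub.fitting_r2 - 1e-10
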