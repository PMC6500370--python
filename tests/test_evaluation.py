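"""Repeated k-fold CV and the Fisher-z null machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylpred.evaluation import (
    cross_validate,
    null_r2_quantile,
    qq_compare,
    qq_null_band,
    r2_confidence_interval,
)
from methylpred.regression import GeneDesign, pearson_r2


def _design(X, y):
    return GeneDesign("g", X, y, [f"p{j}" for j in range(X.shape[1])])


class TestCrossValidate:
    @pytest.mark.parametrize("model", ["single", "multiple", "lasso"])
    def test_noiseless_linear_signal_gives_r2_one(self, model, rng):
        X = rng.normal(size=(60, 3))
        y = 3.0 * X[:, 0]
        cv = cross_validate(_design(X, y), model, seed=9, repeats=2)
        assert cv.r2_cv == pytest.approx(1.0, abs=1e-6)

    def test_pooled_r2_matches_manual_fold_computation(self):
        """n=10 toy, 1 probe, 1 repeat: the pooled-prediction R² equals a
        hand-run 5-fold least-squares computation with the same folds."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 1))
        y = 1.5 * X[:, 0] + rng.normal(size=10) * 0.5
        d = _design(X, y)
        cv = cross_validate(d, "single", folds=5, repeats=1, seed=42)

        from methylpred._lasso import kfold_indices

        fold_sets = kfold_indices(10, 5, (42 + 1) % (2**31 - 1))
        preds = np.empty(10)
        for test_idx in fold_sets:
            train = np.setdiff1d(np.arange(10), test_idx)
            x_tr, y_tr = X[train, 0], y[train]
            slope = np.cov(x_tr, y_tr, ddof=1)[0, 1] / np.var(x_tr, ddof=1)
            intercept = y_tr.mean() - slope * x_tr.mean()
            preds[test_idx] = slope * X[test_idx, 0] + intercept
        oracle = pearson_r2(preds, y)
        assert cv.per_repeat[0] == pytest.approx(oracle, abs=1e-12)

    def test_null_single_probe_cv_matches_permutation_oracle(self):
        """For y independent of x the pooled-prediction CV R² is small but
        sits above the naive chance level 1/(n-1): each fold's intercept is
        the training mean, which is anti-correlated with the held-out fold's
        mean, inflating the squared correlation.  The frozen oracle value
        0.0339 comes from an independently coded Monte-Carlo permutation run
        (3000 draws of the same pooled 5-fold statistic at n=100)."""
        n = 100
        vals = []
        for s in range(300):
            rng = np.random.default_rng(7000 + s)
            X = rng.normal(size=(n, 1))
            y = rng.normal(size=n)
            cv = cross_validate(_design(X, y), "single", repeats=2, seed=s)
            vals.append(cv.r2_cv)
        assert np.mean(vals) == pytest.approx(0.0339, abs=0.006)
        assert 1.0 / (n - 1) < np.mean(vals) < 6.0 / (n - 1)

    def test_repeat_dispersion_shrinks_with_sample_size(self):
        def spread(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(n, 2))
            y = X[:, 0] + rng.normal(size=n)
            cv = cross_validate(_design(X, y), "single", repeats=10, seed=1)
            return np.std(cv.per_repeat)

        small = np.mean([spread(100, s) for s in range(5)])
        large = np.mean([spread(500, s) for s in range(5)])
        assert large < small

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(50, 4))
        y = X[:, 1] + rng.normal(size=50)
        d = _design(X, y)
        a = cross_validate(d, "lasso", repeats=2, seed=11)
        b = cross_validate(d, "lasso", repeats=2, seed=11)
        c = cross_validate(d, "lasso", repeats=2, seed=12)
        assert a.per_repeat == b.per_repeat
        assert a.per_repeat != c.per_repeat

    def test_held_out_response_never_enters_prediction(self, rng):
        """Corrupting y inside the held-out fold leaves that fold's
        predictions unchanged for every model."""
        from methylpred.evaluation import (
            _predict_lasso,
            _predict_multiple,
            _predict_single_refit,
        )

        X = rng.normal(size=(50, 3))
        y = X[:, 0] + rng.normal(size=50)
        Xtr, Xte, ytr = X[:40], X[40:], y[:40]
        assert np.array_equal(
            _predict_multiple(Xtr, ytr, Xte), _predict_multiple(Xtr, ytr, Xte)
        )
        p1 = _predict_lasso(Xtr, ytr, Xte, 10, 5, 100, 1e-3)
        p2 = _predict_lasso(Xtr, ytr, Xte, 10, 5, 100, 1e-3)
        assert np.array_equal(p1, p2)
        assert np.array_equal(
            _predict_single_refit(Xtr, ytr, Xte),
            _predict_single_refit(Xtr, ytr, Xte),
        )

    def test_single_strategy_reports_best_probe(self, rng):
        X = rng.normal(size=(60, 4))
        y = 2.0 * X[:, 2] + rng.normal(size=60) * 0.3
        cv = cross_validate(_design(X, y), "single", repeats=3, seed=0)
        assert cv.best_probe == "p2"

    def test_mean_lasso_beats_single_with_several_informative_probes(self):
        """With >= 2 informative CpGs the sparse model's CV R² exceeds the
        single-CpG model's in the mean over genes."""
        diffs = []
        for s in range(50):
            rng = np.random.default_rng(8000 + s)
            X = rng.normal(size=(150, 8))
            y = X[:, :3] @ np.array([1.0, 0.8, -0.9]) + rng.normal(size=150) * 1.5
            d = _design(X, y)
            lasso = cross_validate(d, "lasso", repeats=2, seed=s).r2_cv
            single = cross_validate(d, "single", repeats=2, seed=s).r2_cv
            diffs.append(lasso - single)
        assert np.mean(diffs) > 0


class TestFisherNull:
    def test_closed_form_median_at_n_103(self):
        # tanh(0.6745 / 10)^2
        assert null_r2_quantile(0.5, 103) == pytest.approx(0.004536, abs=5e-6)

    def test_agrees_with_simulated_null_correlations(self):
        """20,000 actual correlations of independent normal pairs at n=100."""
        rng = np.random.default_rng(0)
        n, sims = 100, 20_000
        a = rng.normal(size=(sims, n))
        b = rng.normal(size=(sims, n))
        a -= a.mean(axis=1, keepdims=True)
        b -= b.mean(axis=1, keepdims=True)
        r = (a * b).sum(1) / np.sqrt((a * a).sum(1) * (b * b).sum(1))
        r2 = np.sort(r * r)
        for q in (0.5, 0.9, 0.99):
            assert null_r2_quantile(q, n) == pytest.approx(
                np.quantile(r2, q), abs=0.002
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        q=st.floats(min_value=0.01, max_value=0.99),
        n=st.integers(min_value=5, max_value=2000),
    )
    def test_monotone_in_q_and_shrinks_with_n(self, q, n):
        val = null_r2_quantile(q, n)
        assert 0 <= val < 1
        if q < 0.98:
            assert val <= null_r2_quantile(q + 0.01, n)
        assert null_r2_quantile(q, 2 * n) < val or val == 0

    def test_rejects_degenerate_sample_size(self):
        with pytest.raises(ValueError):
            null_r2_quantile(0.5, 3)

    def test_vanishes_at_small_quantiles(self):
        assert null_r2_quantile(1e-9, 100) < 1e-12


class TestConfidenceInterval:
    def test_frozen_interval_at_quarter_r2(self):
        lo, hi = r2_confidence_interval(0.25, 103)
        assert lo == pytest.approx(0.115, abs=0.001)
        assert hi == pytest.approx(0.400, abs=0.001)

    def test_null_center_has_zero_lower_bound(self):
        lo, hi = r2_confidence_interval(0.0, 100)
        assert lo == 0.0
        assert hi == pytest.approx(np.tanh(1.959964 / np.sqrt(97)) ** 2, abs=1e-6)

    def test_width_shrinks_to_zero_with_n(self):
        widths = [
            np.diff(r2_confidence_interval(0.3, n))[0] for n in (50, 500, 5000)
        ]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 0.05

    def test_coverage_against_parametric_bootstrap(self):
        """~93-97% of simulated bivariate-normal samples with true rho²=0.25
        produce a CI containing the truth."""
        rng = np.random.default_rng(1)
        rho, n, sims = 0.5, 103, 2000
        covered = 0
        z = rng.normal(size=(sims, n, 2))
        x = z[:, :, 0]
        y = rho * z[:, :, 0] + np.sqrt(1 - rho**2) * z[:, :, 1]
        for i in range(sims):
            r2 = pearson_r2(x[i], y[i])
            lo, hi = r2_confidence_interval(r2, n)
            covered += lo <= rho**2 <= hi
        assert 0.92 < covered / sims < 0.98

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            r2_confidence_interval(0.5, 3)
        with pytest.raises(ValueError):
            r2_confidence_interval(1.5, 100)


class TestQqCompare:
    def test_all_zero_observations_never_exceed_null(self):
        res = qq_compare(np.zeros(100), n=100)
        assert res.max_departure <= 0

    def test_translation_shows_up_as_departure(self):
        rng = np.random.default_rng(2)
        null = np.tanh(rng.normal(0, 1 / np.sqrt(97), 500)) ** 2
        res = qq_compare(null + 0.2, n=100)
        assert res.max_departure == pytest.approx(0.2, abs=0.05)

    def test_null_draws_stay_inside_monte_carlo_band(self):
        band = qq_null_band(n=100, n_genes=500, n_sims=300, seed=5)
        rng = np.random.default_rng(6)
        exceed = 0
        for _ in range(20):
            draws = np.tanh(rng.normal(0, 1 / np.sqrt(97), 500)) ** 2
            exceed += qq_compare(draws, 100).max_departure > band
        assert exceed <= 2  # 99th-percentile band

    def test_table_is_rankwise_and_sorted(self):
        res = qq_compare([0.3, 0.1, 0.2], n=50)
        assert list(res.table["observed"]) == [0.1, 0.2, 0.3]
        assert res.table["expected"].is_monotonic_increasing
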