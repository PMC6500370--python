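"""Out-of-sample evaluation and the Fisher-z null for squared correlations.

Prediction accuracy is estimated by repeated 5-fold cross-validation: each
repeat partitions the samples at random into five folds, every fold is
predicted from a model fit on the other four, and one squared correlation
is computed between the pooled out-of-fold predictions and the observed
expression.  The reported CV R² is the mean of that quantity over repeats.

Under the null of no association, the Fisher transform z = atanh(r) of a
sample correlation is approximately Normal(0, 1/(n-3)); this yields closed
forms for null quantiles of R² and for confidence intervals on the R²
scale, used as the reference line/band in QQ-style comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._lasso import kfold_indices, lasso_cv_select, lasso_penalty_path
from .regression import (
    GeneDesign,
    GeneSkipped,
    _ols_min_norm,
    _standardize,
    pearson_r2,
)

log = logging.getLogger(__name__)

__all__ = [
    "CvResult",
    "QqResult",
    "cross_validate",
    "null_r2_quantile",
    "r2_confidence_interval",
    "qq_compare",
    "qq_null_band",
]

MODELS = ("single", "multiple", "lasso")


@dataclass
class CvResult:
    """Repeated k-fold CV summary for one gene and model."""

    gene: str
    model: str
    r2_cv: float  # mean over repeats; NaN when every repeat was discarded
    per_repeat: list[float] = field(default_factory=list)
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    best_probe: str | None = None  # single model: CpG whose CV R² was kept


def _predict_multiple(Xtr, ytr, Xte):
    coef, intercept, _, _ = _ols_min_norm(Xtr, ytr)
    return Xte @ coef + intercept


def _predict_lasso(Xtr, ytr, Xte, inner_folds, seed, n_alphas, alpha_min_ratio,
                   selection_rule="min_mse"):
    """Refit the full penalty-selection procedure inside the training fold."""
    keep = Xtr.std(axis=0) > 0
    if not keep.any() or ytr.std() == 0:
        return np.full(Xte.shape[0], ytr.mean())
    Xtr = Xtr[:, keep]
    Xte = Xte[:, keep]
    X_std, y_std, xm, xs, ym, ys = _standardize(Xtr, ytr)
    alphas = lasso_penalty_path(X_std, y_std, n_alphas, alpha_min_ratio)
    folds = kfold_indices(Xtr.shape[0], min(inner_folds, Xtr.shape[0]), seed)
    best, coef_path, _ = lasso_cv_select(
        X_std, y_std, alphas, folds, selection_rule=selection_rule
    )
    coef = coef_path[best] * ys / xs
    intercept = ym - float(coef @ xm)
    return Xte @ coef + intercept


def _predict_single_refit(Xtr, ytr, Xte):
    """Re-select the best CpG inside the training portion, then predict."""
    Xc = Xtr - Xtr.mean(axis=0)
    yc = ytr - ytr.mean()
    sx2 = (Xc * Xc).sum(axis=0)
    sy2 = yc @ yc
    cov = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sx2 > 0, cov**2 / np.maximum(sx2 * sy2, 1e-300), -1.0)
    j = int(np.argmax(r2))
    if sx2[j] <= 0:
        return np.full(Xte.shape[0], ytr.mean())
    slope = cov[j] / sx2[j]
    intercept = ytr.mean() - slope * Xtr[:, j].mean()
    return Xte[:, j] * slope + intercept


def _per_cpg_fold_predictions(Xtr, ytr, Xte):
    """Univariate OLS predictions of the held-out fold for every CpG at once."""
    xm = Xtr.mean(axis=0)
    Xc = Xtr - xm
    yc = ytr - ytr.mean()
    sx2 = (Xc * Xc).sum(axis=0)
    cov = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sx2 > 0, cov / np.maximum(sx2, 1e-300), 0.0)
    return (Xte - xm) * slope + ytr.mean()


def cross_validate(
    design: GeneDesign,
    model: str,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    inner_folds: int = 10,
    single_strategy: str = "max_per_cpg",
    pooled: bool = True,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    selection_rule: str = "min_mse",
) -> CvResult:
    """Repeated k-fold cross-validation R² for one gene.

    All model choices internal to training — penalty selection for the
    lasso, best-CpG selection for ``single_strategy='refit'``, and
    standardization parameters — are re-estimated inside each training
    portion, so the held-out fold never leaks into the fit.

    For the single-CpG model the default ``single_strategy='max_per_cpg'``
    runs the CV separately for every CpG and keeps the maximum mean R²
    (each CpG's predictions stay leakage-free, but the final max is taken
    across CpGs on the CV estimates themselves); ``'refit'`` instead
    re-selects the best training-portion CpG inside every fold.

    ``pooled=True`` (default) computes one R² per repeat from the pooled
    out-of-fold predictions; ``pooled=False`` averages per-fold R² instead.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    n = design.n_complete
    if n < 2 * folds:
        raise GeneSkipped(design.gene, f"{n} samples < 2 x {folds} folds")
    X, y = design.X, design.y

    per_cpg_mode = model == "single" and single_strategy == "max_per_cpg"
    per_repeat: list[float] = []
    per_repeat_matrix: list[np.ndarray] = []  # per-CpG mode only

    for r in range(repeats):
        rep_seed = (int(seed) + 1 + r) % (2**31 - 1)
        fold_sets = kfold_indices(n, folds, rep_seed)
        ok = True
        if per_cpg_mode:
            preds = np.empty_like(X)
        else:
            preds = np.empty(n)
        for k, test_idx in enumerate(fold_sets):
            train_idx = np.setdiff1d(np.arange(n), test_idx, assume_unique=False)
            ytr = y[train_idx]
            if ytr.std() == 0:
                log.info("%s repeat %d: constant training response, discarded",
                         design.gene, r)
                ok = False
                break
            Xtr, Xte = X[train_idx], X[test_idx]
            if per_cpg_mode:
                preds[test_idx] = _per_cpg_fold_predictions(Xtr, ytr, Xte)
            elif model == "single":
                preds[test_idx] = _predict_single_refit(Xtr, ytr, Xte)
            elif model == "multiple":
                preds[test_idx] = _predict_multiple(Xtr, ytr, Xte)
            else:
                inner_seed = (rep_seed * folds + k) % (2**31 - 1)
                preds[test_idx] = _predict_lasso(
                    Xtr, ytr, Xte, inner_folds, inner_seed, n_alphas,
                    alpha_min_ratio, selection_rule,
                )
        if not ok:
            continue
        if per_cpg_mode:
            r2_vec = np.array([pearson_r2(preds[:, j], y) for j in range(X.shape[1])])
            per_repeat_matrix.append(r2_vec)
        elif pooled:
            per_repeat.append(pearson_r2(preds, y))
        else:
            fold_r2 = [pearson_r2(preds[idx], y[idx]) for idx in fold_sets]
            per_repeat.append(float(np.mean(fold_r2)))

    best_probe = None
    if per_cpg_mode:
        if per_repeat_matrix:
            mat = np.vstack(per_repeat_matrix)  # repeats x p
            mean_per_cpg = mat.mean(axis=0)
            j = int(np.argmax(mean_per_cpg))
            best_probe = design.probe_ids[j]
            per_repeat = [float(v) for v in mat[:, j]]
    r2_cv = float(np.mean(per_repeat)) if per_repeat else float("nan")
    if not per_repeat:
        log.warning("%s/%s: all CV repeats discarded", design.gene, model)
    return CvResult(
        gene=design.gene,
        model=model,
        r2_cv=r2_cv,
        per_repeat=per_repeat,
        n_folds=folds,
        n_repeats=repeats,
        seed=seed,
        best_probe=best_probe,
    )


def null_r2_quantile(q, n: int):
    """q-quantile of R² = r² under the no-association Fisher-z null.

    With z = atanh(r) ~ Normal(0, 1/(n-3)), the q-quantile of r² is
    tanh(Phi^-1((1+q)/2) / sqrt(n-3))².  Vectorized over ``q``.
    """
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise ValueError("quantiles must lie strictly in (0, 1)")
    z = ndtri((1.0 + q_arr) / 2.0) / np.sqrt(n - 3)
    out = np.tanh(z) ** 2
    return float(out) if np.isscalar(q) else out


def r2_confidence_interval(r2: float, n: int, level: float = 0.95):
    """Fisher-z confidence interval for R², returned on the R² scale.

    The positive root r = +sqrt(r2) is transformed, the symmetric normal
    interval built on the z scale, and both ends mapped back through tanh
    and squared; when the z-interval crosses zero the lower bound is
    clipped to 0.
    """
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    if not 0 <= r2 < 1:
        raise ValueError(f"need 0 <= r2 < 1, got {r2}")
    z = np.arctanh(np.sqrt(r2))
    half = ndtri((1.0 + level) / 2.0) / np.sqrt(n - 3)
    lo_z, hi_z = z - half, z + half
    lower = 0.0 if lo_z <= 0 else float(np.tanh(lo_z) ** 2)
    upper = float(np.tanh(hi_z) ** 2)
    return lower, upper


@dataclass
class QqResult:
    """Rank-wise observed-vs-null comparison of a set of R² values."""

    table: pd.DataFrame  # columns: q, expected, observed
    max_departure: float  # max over ranks of observed - expected


def qq_compare(observed_r2, n: int) -> QqResult:
    """Compare sorted observed R² against null quantiles, rank by rank.

    Rank i of G genes is matched to the null quantile q = (i - 0.5) / G.
    """
    obs = np.sort(np.asarray(observed_r2, dtype=float))
    if obs.size == 0:
        raise ValueError("observed_r2 is empty")
    g = obs.size
    q = (np.arange(1, g + 1) - 0.5) / g
    expected = null_r2_quantile(q, n)
    table = pd.DataFrame({"q": q, "expected": expected, "observed": obs})
    return QqResult(table=table, max_departure=float(np.max(obs - expected)))


def qq_null_band(
    n: int, n_genes: int, n_sims: int = 500, seed: int = 0, upper: float = 0.99
) -> float:
    """Monte-Carlo band for the max QQ departure under the null.

    Simulates ``n_sims`` sets of ``n_genes`` null R² draws via the Fisher
    normal for z, runs :func:`qq_compare` on each, and returns the
    ``upper`` quantile of the max departure.  An observed dataset whose
    departure exceeds this band shows systematic excess over chance.
    """
    rng = np.random.default_rng(seed)
    g = n_genes
    q = (np.arange(1, g + 1) - 0.5) / g
    expected = null_r2_quantile(q, n)
    deps = np.empty(n_sims)
    scale = 1.0 / np.sqrt(n - 3)
    for s in range(n_sims):
        r2 = np.tanh(rng.normal(0.0, scale, g)) ** 2
        deps[s] = np.max(np.sort(r2) - expected)
    return float(np.quantile(deps, upper))
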