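"""Per-gene regression models: best single CpG, all-CpG OLS, sparse LASSO.

Throughout the package R-squared is the squared Pearson correlation between
predicted and observed expression.  For an in-sample OLS fit with intercept
this coincides with the classical 1 - SSE/SST; for shrunken (LASSO) fits and
for out-of-sample predictions the two differ and the squared correlation is
the one reported.

Designs are built per gene by listwise deletion: any sample missing a value
at any of the gene's probes is dropped for that gene only.  Constant
predictors are dropped (and logged) before every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._lasso import kfold_indices, lasso_cv_select, lasso_penalty_path

log = logging.getLogger(__name__)

__all__ = [
    "GeneSkipped",
    "GeneDesign",
    "SingleFit",
    "MultipleFit",
    "LassoFit",
    "build_design",
    "fit_single_best",
    "fit_multiple",
    "fit_lasso",
    "pearson_r2",
]

#: overall-model significance level for multiple regression
DEFAULT_MODEL_ALPHA = 1e-4

#: fewest complete samples for any regression on a gene
MIN_COMPLETE_SAMPLES = 10

#: fewest complete samples for a penalized fit with inner 10-fold CV
MIN_LASSO_SAMPLES = 20


class GeneSkipped(Exception):
    """A gene cannot be modelled; carries the reason for the skip log."""

    def __init__(self, gene: str, reason: str):
        super().__init__(f"{gene}: {reason}")
        self.gene = gene
        self.reason = reason


@dataclass
class GeneDesign:
    """Complete-case predictor matrix and response for one gene."""

    gene: str
    X: np.ndarray  # n_complete x p, no missing values
    y: np.ndarray  # n_complete
    probe_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_complete(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class SingleFit:
    """Per-CpG univariate regressions; the best CpG represents the gene."""

    gene: str
    probe_ids: list[str]
    r2: np.ndarray  # per-probe squared correlation with y
    p_values: np.ndarray  # per-probe slope t-test probability
    best_index: int
    best_probe: str
    best_r2: float


@dataclass
class MultipleFit:
    """All-CpG ordinary least squares with intercept."""

    gene: str
    probe_ids: list[str]
    coefficients: np.ndarray  # length p
    intercept: float
    fitting_r2: float
    overall_p: float  # model F-test; NaN when saturated
    rank_deficient: bool
    significant: bool


@dataclass
class LassoFit:
    """L1-penalized fit; penalty chosen by inner k-fold CV over a fixed path."""

    gene: str
    probe_ids: list[str]
    alphas: np.ndarray  # candidate penalty path (descending)
    alpha_selected: float
    coefficients: np.ndarray  # length p, original (unstandardized) scale
    intercept: float
    n_nonzero: int
    valid: bool  # at least one nonzero non-intercept coefficient
    fitting_r2: float  # NaN when no coefficient survives


def pearson_r2(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when either side is constant."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    pc = predicted - predicted.mean()
    oc = observed - observed.mean()
    denom = np.sqrt((pc @ pc) * (oc @ oc))
    if denom == 0:
        return 0.0
    r = float(pc @ oc) / denom
    r = max(-1.0, min(1.0, r))
    return r * r


def build_design(
    gene: str,
    paired,
    probes: list[str],
    min_samples: int = MIN_COMPLETE_SAMPLES,
) -> GeneDesign:
    """Assemble the complete-case design for one gene.

    Parameters
    ----------
    paired : PairedDataset
        Sample-aligned expression and methylation.
    probes : list of str
        Probe ids to use as predictors (already filtered by class/region).

    Raises
    ------
    GeneSkipped
        If the gene is absent, has no usable probe, fewer than
        ``min_samples`` complete samples, or a constant response.
    """
    if not probes:
        raise GeneSkipped(gene, "no probes")
    expr = paired.expression.values
    if gene not in expr.index:
        raise GeneSkipped(gene, "gene not in expression matrix")
    meth = paired.methylation.values
    missing = [p for p in probes if p not in meth.index]
    if missing:
        raise GeneSkipped(gene, f"probe {missing[0]} not in methylation matrix")
    y_full = expr.loc[gene].to_numpy(dtype=float)
    X_full = meth.loc[probes].to_numpy(dtype=float).T  # samples x probes
    complete = np.isfinite(X_full).all(axis=1) & np.isfinite(y_full)
    X = X_full[complete]
    y = y_full[complete]
    if X.shape[0] < min_samples:
        raise GeneSkipped(
            gene, f"only {X.shape[0]} complete samples (need {min_samples})"
        )
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [p for p, k in zip(probes, keep) if not k]
        log.info("%s: dropping %d constant probe(s): %s", gene, len(dropped), dropped)
    probes_kept = [p for p, k in zip(probes, keep) if k]
    X = X[:, keep]
    if X.shape[1] == 0:
        raise GeneSkipped(gene, "all probes constant")
    if y.std() == 0:
        raise GeneSkipped(gene, "constant expression")
    samples = [s for s, c in zip(paired.sample_ids, complete) if c]
    return GeneDesign(gene, X, y, probes_kept, samples)


def fit_single_best(design: GeneDesign) -> SingleFit:
    """Regress y on each CpG separately; keep the CpG with maximum R².

    Per-probe R² is the squared Pearson correlation (identical to the
    univariate OLS fit R²); the p-value is the slope t-test.  Ties in R²
    go to the first probe in ascending-id order.
    """
    X, y = design.X, design.y
    n = design.n_complete
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r2 = r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    best = int(np.argmax(r2))
    return SingleFit(
        gene=design.gene,
        probe_ids=design.probe_ids,
        r2=r2,
        p_values=p,
        best_index=best,
        best_probe=design.probe_ids[best],
        best_r2=float(r2[best]),
    )


def _ols_min_norm(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; minimum-norm solution when rank deficient.

    Returns (coefficients, intercept, fitted, rank) where rank counts the
    intercept column.
    """
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ sol
    return sol[1:], float(sol[0]), fitted, int(rank)


def fit_multiple(
    design: GeneDesign, alpha: float = DEFAULT_MODEL_ALPHA
) -> MultipleFit:
    """OLS on all of the gene's CpGs simultaneously.

    Rank-deficient designs (including p >= n-1) are fit with the
    minimum-norm least-squares solution and flagged rather than refused;
    such saturated fits interpolate (R² = 1) and their overall F-test is
    undefined, reported as NaN.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= 2:
        raise GeneSkipped(design.gene, "too few samples for multiple regression")
    coef, intercept, fitted, rank = _ols_min_norm(X, y)
    rank_deficient = rank < p + 1
    r2 = pearson_r2(fitted, y)
    df_model = rank - 1
    df_resid = n - rank
    if df_model < 1 or df_resid < 1 or r2 >= 1.0 - 1e-12:
        overall_p = float("nan")
    else:
        f = (r2 / df_model) / ((1.0 - r2) / df_resid)
        overall_p = float(stats.f.sf(f, df_model, df_resid))
    significant = bool(np.isfinite(overall_p) and overall_p < alpha)
    return MultipleFit(
        gene=design.gene,
        probe_ids=design.probe_ids,
        coefficients=coef,
        intercept=intercept,
        fitting_r2=r2,
        overall_p=overall_p,
        rank_deficient=rank_deficient,
        significant=significant,
    )


def _standardize(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    ym = float(y.mean())
    ys = float(y.std())
    return (X - xm) / xs, (y - ym) / ys, xm, xs, ym, ys


def fit_lasso(
    design: GeneDesign,
    inner_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    selection_rule: str = "min_mse",
) -> LassoFit:
    """L1-penalized regression with the penalty chosen by inner k-fold CV.

    Predictors and response are standardized to unit variance before
    fitting; the selected penalty minimizes the inner CV mean squared
    error, with ties going to the larger (sparser) penalty.  Coefficients
    are mapped back to the original predictor scale.  The fit is *valid*
    when at least one non-intercept coefficient is nonzero; the fitting R²
    uses the whole dataset for prediction.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if p < 2:
        raise GeneSkipped(design.gene, "penalized fit needs at least 2 probes")
    if n < MIN_LASSO_SAMPLES:
        raise GeneSkipped(
            design.gene, f"only {n} complete samples (lasso needs {MIN_LASSO_SAMPLES})"
        )
    if y.std() == 0:
        raise GeneSkipped(design.gene, "constant expression")
    X_std, y_std, xm, xs, ym, ys = _standardize(X, y)
    alphas = lasso_penalty_path(X_std, y_std, n_alphas, alpha_min_ratio)
    folds = kfold_indices(n, inner_folds, seed)
    best, coef_path, _ = lasso_cv_select(
        X_std, y_std, alphas, folds, selection_rule=selection_rule
    )
    coef_std = coef_path[best]
    coef = coef_std * ys / xs
    intercept = ym - float(coef @ xm)
    n_nonzero = int(np.count_nonzero(coef_std))
    valid = n_nonzero >= 1
    if valid:
        fitting_r2 = pearson_r2(X @ coef + intercept, y)
    else:
        fitting_r2 = float("nan")
    return LassoFit(
        gene=design.gene,
        probe_ids=design.probe_ids,
        alphas=alphas,
        alpha_selected=float(alphas[best]),
        coefficients=coef,
        intercept=intercept,
        n_nonzero=n_nonzero,
        valid=valid,
        fitting_r2=fitting_r2,
    )
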