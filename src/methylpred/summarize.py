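"""Threshold tables, significance tallies and cross-mode comparisons.

Result rows are plain records (one per gene x model x probe-set mode x
region mode) held in a pandas DataFrame with columns::

    gene, model, probe_set_mode, region_mode, n_complete, p,
    fitting_r2, r2_cv, overall_p, valid, best_probe, n_nonzero

Model comparisons are made only on genes for which a valid LASSO model
exists in the given probe-set mode, so the three models are always counted
over the same gene set.  Threshold counts use strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .evaluation import r2_confidence_interval

log = logging.getLogger(__name__)

__all__ = [
    "RESULT_COLUMNS",
    "SummaryTable",
    "restrict_to_lasso_valid",
    "count_exceeding",
    "percent_of_modeled",
    "count_genes_with_significant_cpg",
    "compare_probe_sets",
    "variability_correlation",
]

RESULT_COLUMNS = [
    "gene",
    "model",
    "probe_set_mode",
    "region_mode",
    "n_complete",
    "p",
    "fitting_r2",
    "r2_cv",
    "overall_p",
    "valid",
    "best_probe",
    "n_nonzero",
]

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3)


@dataclass
class SummaryTable:
    """Counts of genes whose R² exceeds each threshold, per mode and model."""

    counts: pd.DataFrame  # columns: probe_set_mode, model, metric, threshold, count
    n_lasso_valid: dict[str, int] = field(default_factory=dict)
    n_all_genes: int = 0

    def count(self, probe_set_mode: str, model: str, metric: str, threshold: float) -> int:
        df = self.counts
        sel = (
            (df["probe_set_mode"] == probe_set_mode)
            & (df["model"] == model)
            & (df["metric"] == metric)
            & np.isclose(df["threshold"], threshold)
        )
        if not sel.any():
            raise KeyError((probe_set_mode, model, metric, threshold))
        return int(df.loc[sel, "count"].iloc[0])


def restrict_to_lasso_valid(results: pd.DataFrame) -> pd.DataFrame:
    """Keep, per probe-set/region mode, only genes with a valid LASSO model.

    All three models' rows survive for a retained gene, so downstream
    counts compare the models over an identical gene set.
    """
    keys = ["probe_set_mode", "region_mode"]
    kept = []
    for mode_vals, grp in results.groupby(keys, sort=False):
        lasso = grp[(grp["model"] == "lasso") & (grp["valid"].astype("boolean").fillna(False).astype(bool))]
        genes = set(lasso["gene"])
        if not genes:
            log.warning("no valid LASSO model in mode %s", mode_vals)
            continue
        kept.append(grp[grp["gene"].isin(genes)])
    if not kept:
        return results.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def count_exceeding(
    results: pd.DataFrame,
    metric: str,
    thresholds=DEFAULT_THRESHOLDS,
    n_all_genes: int = 0,
) -> SummaryTable:
    """Count genes with R² strictly above each threshold.

    ``metric`` is ``'fit'`` (fitting R²) or ``'cv'`` (cross-validation R²);
    missing R² values never count.
    """
    col = {"fit": "fitting_r2", "cv": "r2_cv"}[metric]
    rows = []
    n_valid: dict[str, int] = {}
    if results.empty:
        return SummaryTable(
            counts=pd.DataFrame(
                columns=["probe_set_mode", "model", "metric", "threshold", "count"]
            ),
            n_lasso_valid={},
            n_all_genes=int(n_all_genes),
        )
    for (mode, model), grp in results.groupby(
        ["probe_set_mode", "model"], sort=False
    ):
        vals = grp[col].to_numpy(dtype=float)
        for thr in thresholds:
            rows.append(
                {
                    "probe_set_mode": mode,
                    "model": model,
                    "metric": metric,
                    "threshold": thr,
                    "count": int(np.nansum(vals > thr)),
                }
            )
    for mode, grp in results.groupby("probe_set_mode", sort=False):
        n_valid[mode] = int(grp["gene"].nunique())
    return SummaryTable(
        counts=pd.DataFrame(rows),
        n_lasso_valid=n_valid,
        n_all_genes=int(n_all_genes),
    )


def percent_of_modeled(count: int, n_models: int) -> float:
    """Percentage of modelled genes, rounded half-away-from-zero to 2 dp."""
    if n_models <= 0:
        raise ValueError("n_models must be positive")
    if not 0 <= count <= n_models:
        raise ValueError(f"count {count} outside [0, {n_models}]")
    pct = Decimal(count) * 100 / Decimal(n_models)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def count_genes_with_significant_cpg(single_fits, alpha: float) -> int:
    """Genes whose best per-CpG p-value is strictly below alpha (nominal)."""
    count = 0
    for fit in single_fits:
        p = np.asarray(fit.p_values, dtype=float)
        if p.size and np.nanmin(p) < alpha:
            count += 1
    return count


def compare_probe_sets(
    results_methylation: pd.Series | dict,
    results_s_and_c: pd.Series | dict,
    results_all: pd.Series | dict,
    n: int,
    level: float = 0.95,
):
    """Per-gene comparison of R² across probe-set modes.

    Inputs map gene -> R² for the methylation-probe, S&C-probe and
    all-probe models; genes lacking a valid model in a mode are simply
    absent there (reported missing, not zero).  For every gene with a
    methylation-mode R², the Fisher-z confidence interval around it is
    computed and the all-probe R² flagged when it falls outside — the
    signature of the excluded probes adding independent signal.

    Returns ``(table, cross_mode_corr)`` where the correlation (across
    genes with both values) measures whether methylation-driven and
    genotype-driven predictability co-occur in the same genes.
    """
    meth = pd.Series(results_methylation, dtype=float)
    snc = pd.Series(results_s_and_c, dtype=float)
    allp = pd.Series(results_all, dtype=float)
    genes = meth.index.union(snc.index).union(allp.index)
    rows = []
    for gene in genes:
        r2_m = meth.get(gene, np.nan)
        r2_s = snc.get(gene, np.nan)
        r2_a = allp.get(gene, np.nan)
        ci_low = ci_high = np.nan
        outside = np.nan
        if np.isfinite(r2_m):
            ci_low, ci_high = r2_confidence_interval(min(r2_m, 1 - 1e-12), n, level)
            if np.isfinite(r2_a):
                outside = bool(r2_a < ci_low or r2_a > ci_high)
        rows.append(
            {
                "gene": gene,
                "r2_methylation": r2_m,
                "r2_s_and_c": r2_s,
                "r2_all": r2_a,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "flag_outside_ci": outside,
            }
        )
    table = pd.DataFrame(rows)
    both = table.dropna(subset=["r2_methylation", "r2_s_and_c"])
    if len(both) >= 3 and both["r2_methylation"].std() > 0 and both["r2_s_and_c"].std() > 0:
        corr = float(np.corrcoef(both["r2_methylation"], both["r2_s_and_c"])[0, 1])
    else:
        log.warning("cross-mode correlation undefined (<3 genes or constant R²)")
        corr = float("nan")
    return table, corr


def variability_correlation(
    per_gene_sd, r2_cv, method: str = "pearson"
):
    """Correlation between per-gene variability and prediction R².

    ``per_gene_sd`` is typically the SD of each gene's expression across
    samples, or of its best single-regression CpG's methylation.  Returns
    ``(correlation, table)``; the correlation is None when fewer than 3
    genes are available or either vector is constant.
    """
    sd = np.asarray(per_gene_sd, dtype=float)
    r2 = np.asarray(r2_cv, dtype=float)
    if sd.shape != r2.shape:
        raise ValueError("sd and r2 vectors differ in length")
    ok = np.isfinite(sd) & np.isfinite(r2)
    table = pd.DataFrame({"sd": sd, "r2_cv": r2})
    if ok.sum() < 3 or np.ptp(sd[ok]) == 0 or np.ptp(r2[ok]) == 0:
        log.warning("variability correlation undefined")
        return None, table
    if method == "pearson":
        corr = float(np.corrcoef(sd[ok], r2[ok])[0, 1])
    elif method == "spearman":
        from scipy.stats import spearmanr

        corr = float(spearmanr(sd[ok], r2[ok]).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return corr, table
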