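"""Reproducible validation experiments on synthetic cohorts.

Three seeded end-to-end experiments exercise the whole stack against
ground truth the generator plants:

* **null calibration** — an all-null cohort; the LASSO CV R² distribution
  must show no systematic excess over the Fisher-z null (QQ departure
  inside a Monte-Carlo band) and essentially never cross 0.3.
* **recovery** — a strong-signal cohort (planted variance explained 0.5);
  the mean LASSO CV R² must land near the planted value, and the model
  ordering must reproduce the expected directions: penalized >= OLS >=
  single CpG out of sample, OLS >= penalized >= single CpG in sample.
* **independence** — methylation-driven and genotype-driven effects
  planted orthogonally; the cross-mode R² correlation must be near zero.

Each function takes a master seed and returns plain dictionaries of the
measured quantities, so they can be asserted in tests or dumped to JSON.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluation import cross_validate, qq_compare, qq_null_band
from .probes import probes_for_gene
from .regression import GeneSkipped, build_design, fit_lasso, fit_multiple, fit_single_best
from .simulate import preset_config, generate_dataset
from .summarize import compare_probe_sets

log = logging.getLogger(__name__)

__all__ = ["run_null_calibration", "run_recovery", "run_independence"]


def run_null_calibration(
    seed: int,
    n_genes: int = 1000,
    repeats: int = 10,
    threshold: float = 0.3,
    band_sims: int = 300,
) -> dict:
    """LASSO CV R² on an all-null cohort vs the Fisher-z reference.

    Returns the fraction of genes whose CV R² exceeds ``threshold``, the
    rank-wise max departure of the observed values from the analytic null
    quantiles, and the 99th-percentile Monte-Carlo band for that departure.
    """
    cfg = preset_config("null_calibration", seed=seed % (2**31 - 1), n_genes=n_genes)
    paired, gene_map, _, truth = generate_dataset(cfg)
    n = paired.n_samples
    values = []
    for gi, gene in enumerate(truth.genes):
        try:
            design = build_design(gene, paired, probes_for_gene(gene, gene_map))
            cv = cross_validate(
                design, "lasso", repeats=repeats, seed=(seed + 17 * gi) % (2**31 - 1)
            )
        except GeneSkipped:
            continue
        if np.isfinite(cv.r2_cv):
            values.append(cv.r2_cv)
    values = np.asarray(values)
    qq = qq_compare(values, n)
    band = qq_null_band(n, len(values), n_sims=band_sims, seed=seed % (2**31 - 1))
    return {
        "n_genes": len(values),
        "fraction_above": float(np.mean(values > threshold)),
        "max_departure": qq.max_departure,
        "band_99": band,
        "mean_r2_cv": float(values.mean()),
    }


def run_recovery(seed: int, n_genes: int = 50, repeats: int = 10) -> dict:
    """Fit and cross-validate all three models on the strong-signal cohort.

    Returns per-model means of fitting and CV R² over the cohort's genes.
    """
    cfg = preset_config("recovery", seed=seed % (2**31 - 1), n_genes=n_genes)
    paired, gene_map, _, truth = generate_dataset(cfg)
    fit_r2 = {"single": [], "multiple": [], "lasso": []}
    cv_r2 = {"single": [], "multiple": [], "lasso": []}
    for gi, gene in enumerate(truth.genes):
        try:
            design = build_design(gene, paired, probes_for_gene(gene, gene_map))
        except GeneSkipped:
            continue
        fit_r2["single"].append(fit_single_best(design).best_r2)
        fit_r2["multiple"].append(fit_multiple(design).fitting_r2)
        lasso = fit_lasso(design, seed=(seed + 13 * gi) % (2**31 - 1))
        if lasso.valid:
            fit_r2["lasso"].append(lasso.fitting_r2)
        for model in cv_r2:
            cv = cross_validate(
                design, model, repeats=repeats,
                seed=(seed + 29 * gi) % (2**31 - 1),
            )
            if np.isfinite(cv.r2_cv):
                cv_r2[model].append(cv.r2_cv)
    return {
        "n_genes": len(cv_r2["lasso"]),
        "mean_fit": {m: float(np.mean(v)) for m, v in fit_r2.items()},
        "mean_cv": {m: float(np.mean(v)) for m, v in cv_r2.items()},
        "planted_r2": 0.5,
    }


def run_independence(seed: int, n_genes: int = 200, repeats: int = 3) -> dict:
    """Cross-mode R² correlation under orthogonally planted effects.

    CV R² (not in-sample fitting R²) is correlated across genes between
    the methylation-probe and S&C-probe models: in-sample values share an
    overfitting term proportional to the residual variance, which would
    bias the correlation negative, while CV values do not.  All genes
    enter the correlation — filtering on model validity would distort the
    factorial balance of the planted effects through selection.
    """
    cfg = preset_config("independence", seed=seed % (2**31 - 1), n_genes=n_genes)
    paired, gene_map, _, truth = generate_dataset(cfg)
    r2 = {"methylation": {}, "s_and_c": {}}
    for gi, gene in enumerate(truth.genes):
        for mode in r2:
            try:
                design = build_design(
                    gene, paired, probes_for_gene(gene, gene_map, mode, "all")
                )
                cv = cross_validate(
                    design, "lasso", repeats=repeats,
                    seed=(seed + 31 * gi) % (2**31 - 1),
                )
            except GeneSkipped:
                continue
            if np.isfinite(cv.r2_cv):
                r2[mode][gene] = cv.r2_cv
    _, corr = compare_probe_sets(
        r2["methylation"], r2["s_and_c"], {}, paired.n_samples
    )
    n_pairs = len(set(r2["methylation"]) & set(r2["s_and_c"]))
    return {"n_genes": n_genes, "n_pairs": n_pairs, "cross_mode_corr": float(corr)}
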