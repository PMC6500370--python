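"""End-to-end orchestration: load -> map -> fit -> cross-validate -> summarize.

A run is described by a :class:`RunConfig` (input paths or a generator
preset, the modes and models to fit, the fixed CV constants) and produces
a directory of TSVs: per-gene model results, CV results, threshold
summary tables, a QQ table against the Fisher-z null, the probe-set
comparison table, a skip log and a run log.  Every output carries a
header comment with the package version, the config hash and the master
seed; a run is deterministic given its seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import cross_validate, qq_compare
from .io import (
    align_samples,
    read_expression_matrix,
    read_methylation_matrix,
)
from .probes import (
    build_gene_probe_map,
    classify_probes,
    load_exclusion_list,
    load_probe_annotation,
    probes_for_gene,
)
from .regression import (
    GeneSkipped,
    build_design,
    fit_lasso,
    fit_multiple,
    fit_single_best,
)
from .simulate import generate_dataset, preset_config, write_dataset
from .summarize import (
    RESULT_COLUMNS,
    compare_probe_sets,
    count_exceeding,
    restrict_to_lasso_valid,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "parse_config_file", "run_pipeline"]

_LIST_FIELDS = {"probe_set_modes", "region_modes", "models", "thresholds"}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study constants."""

    expression_path: str | None = None
    methylation_path: str | None = None
    annotation_path: str | None = None
    exclusion_path: str | None = None
    preset: str | None = None
    scale: str = "beta"
    dialect: str = "plain_tsv"
    probe_set_modes: tuple[str, ...] = ("methylation",)
    region_modes: tuple[str, ...] = ("all",)
    models: tuple[str, ...] = ("single", "multiple", "lasso")
    folds: int = 5
    repeats: int = 10
    inner_folds: int = 10
    thresholds: tuple[float, ...] = (0.1, 0.2, 0.3)
    alpha_model: float = 1e-4
    single_cv_strategy: str = "max_per_cpg"
    run_cv: bool = True
    min_samples: int = 10
    seed: int = 0
    outdir: str = "methylpred_run"

    def validate(self) -> None:
        if not self.models:
            raise ValueError("at least one model is required")
        if not self.probe_set_modes:
            raise ValueError("at least one probe_set_mode is required")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be ascending")
        if self.preset is None and not (
            self.expression_path and self.methylation_path and self.annotation_path
        ):
            raise ValueError("either a preset or input paths must be given")

    def hash(self) -> str:
        # outdir is excluded: two runs of the same analysis into different
        # directories must produce identical files
        payload = repr(
            sorted(
                (f.name, getattr(self, f.name))
                for f in fields(self)
                if f.name != "outdir"
            )
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """In-memory view of a completed run."""

    config: RunConfig
    results: pd.DataFrame  # per gene x model x mode records
    summaries: dict[str, object] = field(default_factory=dict)
    qq_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparison: pd.DataFrame | None = None
    cross_mode_corr: float = float("nan")
    skipped: pd.DataFrame | None = None
    outdir: Path | None = None


def parse_config_file(path: str | Path) -> RunConfig:
    """Read a flat ``key: value`` config file into a RunConfig.

    List values are comma-separated; '#' starts a comment.
    """
    known = {f.name: f for f in fields(RunConfig)}
    kwargs: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, val = (s.strip() for s in line.split(":", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in _LIST_FIELDS:
            items = [v.strip() for v in val.split(",") if v.strip()]
            if key == "thresholds":
                kwargs[key] = tuple(float(v) for v in items)
            else:
                kwargs[key] = tuple(items)
        elif key in ("folds", "repeats", "inner_folds", "seed", "min_samples"):
            kwargs[key] = int(val)
        elif key == "alpha_model":
            kwargs[key] = float(val)
        elif key == "run_cv":
            kwargs[key] = val.lower() in ("1", "true", "yes")
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def _load_inputs(config: RunConfig):
    if config.preset:
        cfg = preset_config(config.preset, seed=config.seed)
        paired, gene_map, classification, truth = generate_dataset(cfg)
        return paired, gene_map, classification, truth
    expr = read_expression_matrix(config.expression_path, dialect=config.dialect)
    meth = read_methylation_matrix(
        config.methylation_path, scale=config.scale, dialect=config.dialect
    )
    paired = align_samples(expr, meth)
    annotations = load_probe_annotation(config.annotation_path)
    exclusion = (
        load_exclusion_list(config.exclusion_path) if config.exclusion_path else set()
    )
    classification = classify_probes(
        paired.methylation.probe_ids, exclusion, provenance=config.exclusion_path
    )
    gene_map = build_gene_probe_map(
        annotations, classification, paired.methylation.probe_ids
    )
    return paired, gene_map, classification, None


def _gene_seed(master: int, index: int, salt: int = 0) -> int:
    return (int(master) + 99991 * salt + 7919 * index + 1) % (2**31 - 1)


def fit_gene(
    gene: str,
    design,
    config: RunConfig,
    gene_index: int,
    probe_set_mode: str,
    region_mode: str,
):
    """Fit and cross-validate every requested model on one design."""
    rows = []
    lasso_seed = _gene_seed(config.seed, gene_index, salt=1)
    cv_seed = _gene_seed(config.seed, gene_index, salt=2)
    for model in config.models:
        row = {
            "gene": gene,
            "model": model,
            "probe_set_mode": probe_set_mode,
            "region_mode": region_mode,
            "n_complete": design.n_complete,
            "p": design.p,
            "fitting_r2": np.nan,
            "r2_cv": np.nan,
            "overall_p": np.nan,
            "valid": np.nan,
            "best_probe": None,
            "n_nonzero": np.nan,
        }
        try:
            if model == "single":
                fit = fit_single_best(design)
                row["fitting_r2"] = fit.best_r2
                row["best_probe"] = fit.best_probe
                row["overall_p"] = float(np.min(fit.p_values))
                row["_single_fit"] = fit
            elif model == "multiple":
                if design.p < 2:
                    raise GeneSkipped(gene, "multiple regression needs >= 2 probes")
                fit = fit_multiple(design, alpha=config.alpha_model)
                row["fitting_r2"] = fit.fitting_r2
                row["overall_p"] = fit.overall_p
                row["valid"] = not fit.rank_deficient
            elif model == "lasso":
                fit = fit_lasso(design, inner_folds=config.inner_folds, seed=lasso_seed)
                row["fitting_r2"] = fit.fitting_r2
                row["valid"] = fit.valid
                row["n_nonzero"] = fit.n_nonzero
            else:
                raise ValueError(f"unknown model {model!r}")
            if config.run_cv:
                cv = cross_validate(
                    design,
                    model,
                    folds=config.folds,
                    repeats=config.repeats,
                    seed=cv_seed,
                    inner_folds=config.inner_folds,
                    single_strategy=config.single_cv_strategy,
                )
                row["r2_cv"] = cv.r2_cv
        except GeneSkipped as exc:
            row["_skip_reason"] = exc.reason
        rows.append(row)
    return rows


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a full run and write its output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("methylpred")
    root.addHandler(handler)
    t0 = time.time()
    note = f"methylpred {__version__} seed={config.seed} config={config.hash()}"
    try:
        paired, gene_map, classification, truth = _load_inputs(config)
        log.info(
            "loaded %d genes x %d samples, %d probes",
            len(paired.expression.gene_ids),
            paired.n_samples,
            len(paired.methylation.probe_ids),
        )
        if config.preset and truth is not None:
            write_dataset(paired, classification, truth, outdir / "dataset", note)

        all_rows: list[dict] = []
        skip_rows: list[dict] = []
        single_fits: dict[tuple, list] = {}
        for probe_set_mode in config.probe_set_modes:
            for region_mode in config.region_modes:
                n_fit = 0
                for gi, gene in enumerate(paired.expression.gene_ids):
                    probes = probes_for_gene(
                        gene, gene_map, probe_set_mode, region_mode
                    )
                    try:
                        design = build_design(
                            gene, paired, probes, min_samples=config.min_samples
                        )
                    except GeneSkipped as exc:
                        skip_rows.append(
                            {
                                "gene": gene,
                                "probe_set_mode": probe_set_mode,
                                "region_mode": region_mode,
                                "reason": exc.reason,
                            }
                        )
                        continue
                    rows = fit_gene(
                        gene, design, config, gi, probe_set_mode, region_mode
                    )
                    for row in rows:
                        reason = row.pop("_skip_reason", None)
                        if reason:
                            skip_rows.append(
                                {
                                    "gene": gene,
                                    "probe_set_mode": probe_set_mode,
                                    "region_mode": region_mode,
                                    "reason": f"{row['model']}: {reason}",
                                }
                            )
                        sf = row.pop("_single_fit", None)
                        if sf is not None:
                            single_fits.setdefault(
                                (probe_set_mode, region_mode), []
                            ).append(sf)
                        all_rows.append(row)
                    n_fit += 1
                log.info(
                    "mode %s/%s: %d genes fitted", probe_set_mode, region_mode, n_fit
                )

        results = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
        skipped = pd.DataFrame(skip_rows, columns=["gene", "probe_set_mode",
                                                   "region_mode", "reason"])
        restricted = restrict_to_lasso_valid(results) if "lasso" in config.models else results

        summaries: dict[str, object] = {}
        n_all = len(paired.expression.gene_ids)
        for metric in ("fit", "cv") if config.run_cv else ("fit",):
            summaries[metric] = count_exceeding(
                restricted, metric, config.thresholds, n_all_genes=n_all
            )

        qq_tables: dict[str, pd.DataFrame] = {}
        if config.run_cv and "lasso" in config.models:
            for mode, grp in restricted[restricted["model"] == "lasso"].groupby(
                "probe_set_mode"
            ):
                vals = grp["r2_cv"].dropna().to_numpy()
                if vals.size:
                    qq = qq_compare(vals, paired.n_samples)
                    qq_tables[str(mode)] = qq.table

        comparison = None
        corr = float("nan")
        wanted = {"methylation", "s_and_c", "all"}
        if wanted <= set(config.probe_set_modes) and "lasso" in config.models:
            metric_col = "r2_cv" if config.run_cv else "fitting_r2"
            lasso = results[
                (results["model"] == "lasso") & (results["valid"].astype("boolean").fillna(False).astype(bool))
            ]

            def _mode_series(mode):
                grp = lasso[lasso["probe_set_mode"] == mode]
                return grp.set_index("gene")[metric_col].dropna()

            comparison, corr = compare_probe_sets(
                _mode_series("methylation"),
                _mode_series("s_and_c"),
                _mode_series("all"),
                paired.n_samples,
            )

        # --- write outputs -------------------------------------------------
        def _write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with path.open("w") as fh:
                fh.write(f"# {note}\n")
                df.to_csv(fh, sep="\t", index=False, na_rep="NA")

        _write(results, "gene_results.tsv")
        _write(skipped, "skipped_genes.tsv")
        for metric, table in summaries.items():
            _write(table.counts, f"summary_{metric}.tsv")
        for mode, table in qq_tables.items():
            _write(table, f"qq_{mode}.tsv")
        if comparison is not None:
            _write(comparison, "probe_set_comparison.tsv")
        log.info("run finished in %.1f s", time.time() - t0)
        return RunResult(
            config=config,
            results=results,
            summaries=summaries,
            qq_tables=qq_tables,
            comparison=comparison,
            cross_mode_corr=corr,
            skipped=skipped,
            outdir=outdir,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
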