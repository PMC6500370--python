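"""Synthetic paired methylation/expression cohorts with planted truth.

The generator emulates the structure of population methylation studies on
450K-style arrays: per gene, a block of adjacently correlated CpG probes
(AR(1) on a latent Gaussian scale), observed either as beta values through
a base-2 logistic link or directly as M values; a fraction of probes
behave like genotypes (three clusters at Hardy-Weinberg frequencies, the
signature of SNP-affected or cross-hybridizing probes); expression is a
sparse linear function of a few causal probes plus Gaussian noise, with
the noise variance set so the population variance explained equals each
gene's drawn target R²; methylation entries may be missing completely at
random.

Every run emits a :class:`TruthSet` recording the causal probes, effect
sizes and planted R² per gene, so recovery and calibration can be checked
against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MethylationMatrix, PairedDataset, m_to_beta, write_matrix
from .probes import (
    GeneProbeMap,
    ProbeAnnotation,
    ProbeClassification,
    build_gene_probe_map,
    classify_probes,
)

log = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GeneTruth",
    "TruthSet",
    "generate_dataset",
    "planted_r2",
    "preset_config",
    "write_dataset",
    "PRESETS",
]

_REGION_WEIGHTS = {
    "TSS1500": 0.15,
    "TSS200": 0.15,
    "5'UTR": 0.10,
    "1stExon": 0.10,
    "Body": 0.40,
    "3'UTR": 0.10,
}

#: latent draws used to estimate population signal variance on the beta scale
_VAR_MC_DRAWS = 20_000


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``target_r2`` accepts a point mass (float), a ``("uniform", lo, hi)``
    tuple, or a mixture as a list of ``(weight, spec)`` pairs; draws are
    per gene and capped at 0.9.  ``effect_class`` restricts causal probes
    to one probe class, so methylation-driven and genotype-driven signal
    can be planted separately.
    """

    n_samples: int = 200
    n_genes: int = 200
    probes_per_gene: tuple[int, int] = (3, 60)  # inclusive uniform range
    cpg_correlation: float = 0.5  # AR(1) rho on the latent scale
    scale: str = "beta"
    fraction_s_and_c: float = 0.29  # share of array probes in the S&C class
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_r2: object = ((0.5, 0.0), (0.5, ("uniform", 0.0, 0.9)))
    #: when set, genotype-like (S&C) probes carry their own effects with this
    #: independently drawn per-gene target R², alongside the methylation ones
    target_r2_s_and_c: object | None = None
    #: "random" draws both targets independently; "balanced" crosses two
    #: levels per class in an exact 2x2 factorial over genes, so the planted
    #: effects are empirically orthogonal by construction
    target_assignment: str = "random"
    balanced_levels: tuple[float, float] = (0.0, 0.35)
    n_causal: int = 3
    promoter_negative_prob: float = 0.8
    body_positive_prob: float = 0.8
    effect_class: str = "methylation"  # methylation | s_and_c | any
    genotype_delta: float = 1.0  # latent separation of genotype clusters
    genotype_jitter: float = 0.15
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.effect_class not in ("methylation", "s_and_c", "any"):
            raise ValueError(f"unknown effect_class {self.effect_class!r}")
        for name in ("fraction_s_and_c", "missing_rate",
                     "promoter_negative_prob", "body_positive_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1 < self.cpg_correlation < 1:
            raise ValueError("cpg_correlation must lie in (-1, 1)")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene range invalid")
        if self.n_causal < 0 or self.n_causal > hi:
            raise ValueError("n_causal outside probes_per_gene range")
        if _max_target(self.target_r2) >= 1:
            raise ValueError("target R² must be < 1")
        if self.n_causal == 0 and _max_target(self.target_r2) > 0:
            raise ValueError("positive target R² requires n_causal >= 1")
        if self.target_r2_s_and_c is not None:
            if _max_target(self.target_r2_s_and_c) >= 1:
                raise ValueError("S&C target R² must be < 1")
            if self.n_causal == 0 and _max_target(self.target_r2_s_and_c) > 0:
                raise ValueError("positive S&C target R² requires n_causal >= 1")
            if self.fraction_s_and_c == 0 and _max_target(self.target_r2_s_and_c) > 0:
                raise ValueError("S&C effects need fraction_s_and_c > 0")
        if self.target_assignment not in ("random", "balanced"):
            raise ValueError(f"unknown target_assignment {self.target_assignment!r}")
        if self.target_assignment == "balanced":
            if self.target_r2_s_and_c is None:
                raise ValueError("balanced assignment needs target_r2_s_and_c")
            if not all(0 <= v < 0.5 for v in self.balanced_levels):
                raise ValueError("balanced levels must lie in [0, 0.5)")
        if self.n_samples < 10 or self.n_genes < 1:
            raise ValueError("need n_samples >= 10 and n_genes >= 1")


def _max_target(spec) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, tuple) and spec and spec[0] == "uniform":
        return float(spec[2])
    return max(_max_target(s) for _, s in spec)


def _draw_target(spec, rng: np.random.Generator) -> float:
    if isinstance(spec, (int, float)):
        return min(float(spec), 0.9)
    if isinstance(spec, tuple) and spec and spec[0] == "uniform":
        return min(float(rng.uniform(spec[1], spec[2])), 0.9)
    weights = np.array([w for w, _ in spec], dtype=float)
    weights /= weights.sum()
    k = rng.choice(len(weights), p=weights)
    return _draw_target(list(spec)[k][1], rng)


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene: str
    probe_ids: list[str]
    regions: dict[str, str]
    classes: dict[str, str]
    causal_probes: list[str]
    effects: np.ndarray  # aligned with causal_probes
    var_signal: float
    var_noise: float
    planted_r2: float
    planted_r2_methylation: float = 0.0
    planted_r2_s_and_c: float = 0.0


@dataclass
class TruthSet:
    """Per-gene planted effects and theoretical variance explained."""

    config: GeneratorConfig
    genes: dict[str, GeneTruth] = field(default_factory=dict)


def planted_r2(truth: TruthSet, gene: str) -> float:
    """Population variance explained, var(Xb) / (var(Xb) + var(eps))."""
    if gene not in truth.genes:
        raise ValueError(f"unknown gene {gene!r}")
    return truth.genes[gene].planted_r2


def _gene_latents(
    rng: np.random.Generator,
    n: int,
    p: int,
    rho: float,
    is_genotype: np.ndarray,
    mafs: np.ndarray,
    delta: float,
    jitter: float,
) -> np.ndarray:
    """Latent probe values: AR(1) Gaussians, genotype columns overwritten."""
    z = np.empty((n, p))
    z[:, 0] = rng.standard_normal(n)
    innov = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        z[:, j] = rho * z[:, j - 1] + innov * rng.standard_normal(n)
    for j in np.flatnonzero(is_genotype):
        q = mafs[j]
        geno = rng.choice(
            3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2]
        ).astype(float)
        z[:, j] = (geno - 1.0) * delta + rng.normal(0.0, jitter, n)
    return z


def _population_signal_var(
    cfg: GeneratorConfig,
    var_rng: np.random.Generator,
    p: int,
    causal_idx: np.ndarray,
    beta: np.ndarray,
    is_genotype: np.ndarray,
    mafs: np.ndarray,
) -> float:
    """Population var of the causal linear combination of observed probes.

    On the M scale (observed = latent) this is exact from the AR(1)
    covariance plus independent genotype-column variances; on the beta
    scale the logistic link has no closed form, so a large seeded
    Monte-Carlo draw of the latent model is used.
    """
    rho = cfg.cpg_correlation
    if cfg.scale == "m":
        var = 0.0
        for a, ia in zip(beta, causal_idx):
            for b, ib in zip(beta, causal_idx):
                if is_genotype[ia] or is_genotype[ib]:
                    if ia == ib:
                        q = mafs[ia]
                        var += a * b * (
                            cfg.genotype_delta**2 * 2 * q * (1 - q)
                            + cfg.genotype_jitter**2
                        )
                else:
                    var += a * b * rho ** abs(int(ia) - int(ib))
        return float(var)
    z = _gene_latents(
        var_rng, _VAR_MC_DRAWS, p, rho, is_genotype, mafs,
        cfg.genotype_delta, cfg.genotype_jitter,
    )
    x = m_to_beta(z[:, causal_idx])
    return float(np.var(x @ beta))


def generate_dataset(config: GeneratorConfig):
    """Simulate a paired cohort.

    Returns ``(PairedDataset, GeneProbeMap, ProbeClassification, TruthSet)``;
    bit-identical for identical configs (all randomness flows from
    ``config.seed``).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    region_names = list(_REGION_WEIGHTS)
    region_p = np.array(list(_REGION_WEIGHTS.values()))

    expr_rows = {}
    meth_blocks = []
    probe_ids_all: list[str] = []
    annotations: dict[str, ProbeAnnotation] = {}
    exclusion: set[str] = set()
    truth = TruthSet(config=cfg)

    for g in range(cfg.n_genes):
        gene = f"G{g + 1:04d}"
        p = int(rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1))
        probe_ids = [f"cg{g + 1:05d}{j + 1:03d}" for j in range(p)]
        regions = list(rng.choice(region_names, size=p, p=region_p))
        is_genotype = rng.random(p) < cfg.fraction_s_and_c
        mafs = rng.uniform(*cfg.maf_range, size=p)

        z = _gene_latents(
            rng, n, p, cfg.cpg_correlation, is_genotype, mafs,
            cfg.genotype_delta, cfg.genotype_jitter,
        )
        X = m_to_beta(z) if cfg.scale == "beta" else z

        var_rng = np.random.default_rng((cfg.seed * 1_000_003 + g) % (2**31 - 1))

        def _draw_effects(eligible: np.ndarray, target: float):
            """Causal subset, signed raw effects and their population variance."""
            k = min(cfg.n_causal, eligible.size)
            if target <= 0 or k == 0:
                if target > 0:
                    log.info("%s: no eligible causal probe, planting null", gene)
                return np.array([], dtype=int), np.array([]), 0.0, 0.0
            idx = np.sort(rng.choice(eligible, size=k, replace=False))
            raw = rng.uniform(0.5, 1.5, size=k)
            for i, j in enumerate(idx):
                grp = regions[j]
                if grp in ("TSS1500", "TSS200", "5'UTR", "1stExon"):
                    neg = rng.random() < cfg.promoter_negative_prob
                elif grp == "Body":
                    neg = rng.random() >= cfg.body_positive_prob
                else:
                    neg = rng.random() < 0.5
                if neg:
                    raw[i] = -raw[i]
            var = _population_signal_var(cfg, var_rng, p, idx, raw, is_genotype, mafs)
            return idx, raw, var, target

        if cfg.target_r2_s_and_c is not None:
            # independent methylation-driven and genotype-driven components,
            # expressed as variance fractions of a unit-variance response
            if cfg.target_assignment == "balanced":
                lo, hi = cfg.balanced_levels
                t_m = hi if g % 2 else lo
                t_s = hi if (g // 2) % 2 else lo
            else:
                t_m = _draw_target(cfg.target_r2, rng)
                t_s = _draw_target(cfg.target_r2_s_and_c, rng)
                if t_m + t_s > 0.9:
                    shrink = 0.9 / (t_m + t_s)
                    t_m, t_s = t_m * shrink, t_s * shrink
            idx_m, raw_m, v_m, t_m = _draw_effects(np.flatnonzero(~is_genotype), t_m)
            idx_s, raw_s, v_s, t_s = _draw_effects(np.flatnonzero(is_genotype), t_s)
            beta_m = raw_m * np.sqrt(t_m / v_m) if t_m > 0 else raw_m
            beta_s = raw_s * np.sqrt(t_s / v_s) if t_s > 0 else raw_s
            causal_idx = np.concatenate([idx_m, idx_s]).astype(int)
            beta = np.concatenate([beta_m, beta_s])
            var_signal = t_m + t_s
            var_noise = 1.0 - var_signal
            signal = X[:, causal_idx] @ beta if causal_idx.size else np.zeros(n)
            planted_m, planted_s = t_m, t_s
        else:
            target = _draw_target(cfg.target_r2, rng)
            if cfg.effect_class == "any":
                eligible = np.arange(p)
            elif cfg.effect_class == "s_and_c":
                eligible = np.flatnonzero(is_genotype)
            else:
                eligible = np.flatnonzero(~is_genotype)
            causal_idx, beta, var_signal, target = _draw_effects(eligible, target)
            if target > 0:
                var_noise = var_signal * (1.0 - target) / target
                signal = X[:, causal_idx] @ beta
            else:
                var_signal = 0.0
                var_noise = 1.0
                signal = np.zeros(n)
            planted_m = target if cfg.effect_class == "methylation" else 0.0
            planted_s = target if cfg.effect_class == "s_and_c" else 0.0
        y = signal + rng.normal(0.0, np.sqrt(var_noise), n)

        expr_rows[gene] = y
        meth_blocks.append(pd.DataFrame(X.T, index=probe_ids, columns=sample_ids))
        probe_ids_all.extend(probe_ids)
        for j, pid in enumerate(probe_ids):
            annotations[pid] = ProbeAnnotation(pid, (gene,), (regions[j],))
            if is_genotype[j]:
                exclusion.add(pid)
        denom = var_signal + var_noise
        truth.genes[gene] = GeneTruth(
            gene=gene,
            probe_ids=probe_ids,
            regions={pid: regions[j] for j, pid in enumerate(probe_ids)},
            classes={
                pid: ("s_and_c" if is_genotype[j] else "methylation")
                for j, pid in enumerate(probe_ids)
            },
            causal_probes=[probe_ids[j] for j in causal_idx],
            effects=beta,
            var_signal=var_signal,
            var_noise=var_noise,
            planted_r2=var_signal / denom if denom > 0 else 0.0,
            planted_r2_methylation=planted_m,
            planted_r2_s_and_c=planted_s,
        )

    meth = pd.concat(meth_blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(meth.shape) < cfg.missing_rate
        meth = meth.mask(mask)
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=sample_ids)

    paired = PairedDataset(
        ExpressionMatrix(expr),
        MethylationMatrix(meth, scale=cfg.scale),
        sample_ids,
    )
    classification = classify_probes(probe_ids_all, exclusion, provenance="simulated")
    gene_map = build_gene_probe_map(annotations, classification, probe_ids_all)
    return paired, gene_map, classification, truth


PRESETS: dict[str, GeneratorConfig] = {
    # beta-value cohort with missing entries, the adipose-tissue layout
    "adipose_like": GeneratorConfig(
        n_samples=200, n_genes=200, scale="beta", missing_rate=0.01, seed=11
    ),
    # M-value cohorts without missing values
    "pbmc_like": GeneratorConfig(
        n_samples=100, n_genes=200, scale="m", missing_rate=0.0, seed=12
    ),
    "lcl_like": GeneratorConfig(
        n_samples=280, n_genes=200, scale="m", missing_rate=0.0, seed=13
    ),
    # all-null cohort for calibration of the CV machinery
    "null_calibration": GeneratorConfig(
        n_samples=100,
        n_genes=1000,
        probes_per_gene=(3, 20),
        scale="m",
        target_r2=0.0,
        n_causal=0,
        fraction_s_and_c=0.0,
        missing_rate=0.0,
        seed=21,
    ),
    # strong-signal cohort for recovery of planted variance explained
    "recovery": GeneratorConfig(
        n_samples=500,
        n_genes=50,
        probes_per_gene=(20, 20),
        cpg_correlation=0.3,
        scale="m",
        target_r2=0.5,
        n_causal=3,
        fraction_s_and_c=0.0,
        missing_rate=0.0,
        seed=22,
    ),
    # methylation- and genotype-driven effects planted orthogonally (exact
    # 2x2 factorial of presence/absence over genes) for the cross-mode
    # independence comparison
    "independence": GeneratorConfig(
        n_samples=200,
        n_genes=200,
        probes_per_gene=(10, 20),
        scale="m",
        target_r2=0.35,
        target_r2_s_and_c=0.35,
        target_assignment="balanced",
        balanced_levels=(0.0, 0.35),
        n_causal=2,
        fraction_s_and_c=0.4,
        missing_rate=0.0,
        seed=23,
    ),
}


def preset_config(name: str, seed: int | None = None, **overrides) -> GeneratorConfig:
    """Fetch a named preset, optionally reseeded or with fields overridden."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else replace(cfg)


def write_dataset(
    paired: PairedDataset,
    classification: ProbeClassification,
    truth: TruthSet,
    outdir: str | Path,
    header_note: str = "",
) -> dict[str, Path]:
    """Write the cohort as the TSV formats the readers consume.

    Emits expression.tsv, methylation.tsv, annotation.tsv, exclusion.txt
    and truth.tsv under ``outdir``; returns the path of each file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "annotation": outdir / "annotation.tsv",
        "exclusion": outdir / "exclusion.txt",
        "truth": outdir / "truth.tsv",
    }
    write_matrix(paired.expression.values, paths["expression"], header_note)
    write_matrix(paired.methylation.values, paths["methylation"], header_note)
    ann_rows = []
    for gene, gt in truth.genes.items():
        for pid in gt.probe_ids:
            ann_rows.append(
                {"probe_id": pid, "UCSC_RefGene_Name": gene,
                 "UCSC_RefGene_Group": gt.regions[pid]}
            )
    pd.DataFrame(ann_rows).to_csv(paths["annotation"], sep="\t", index=False)
    with paths["exclusion"].open("w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        for pid in sorted(classification.probe_ids("s_and_c")):
            fh.write(pid + "\n")
    truth_rows = [
        {
            "gene": gt.gene,
            "causal_probes": ";".join(gt.causal_probes),
            "effects": ";".join(f"{b:.6g}" for b in gt.effects),
            "planted_r2": gt.planted_r2,
            "planted_r2_methylation": gt.planted_r2_methylation,
            "planted_r2_s_and_c": gt.planted_r2_s_and_c,
            "var_signal": gt.var_signal,
            "var_noise": gt.var_noise,
        }
        for gt in truth.genes.values()
    ]
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
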