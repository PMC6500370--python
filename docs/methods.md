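# Methods

## Data model

The unit of analysis is a **paired cohort**: an expression matrix
(genes × samples, log-scale normalized) and a methylation matrix (CpG
probes × samples) restricted to their common samples, in expression
order.  Methylation is taken on whichever scale the source provides —
beta values in [0, 1] or M values (log2(beta/(1−beta))) — and never
converted automatically; `beta_to_m` / `m_to_beta` are explicit opt-in
utilities (clip ε = 10⁻⁶ before the logit).  Missing methylation cells
are kept as NaN at load time and handled per gene by listwise deletion:
a sample missing any of a gene's probes is dropped for that gene only,
never imputed.  Expression rows sharing a gene symbol (multiple array
probesets) are collapsed by per-sample mean — a pragmatic stand-in where
the platform mapping is many-to-one; the collapse is logged.

Probes map to genes through manifest-style annotation
(`UCSC_RefGene_Name` / `UCSC_RefGene_Group`, semicolon-joined and
deduplicated per gene–group pair).  A multi-gene probe contributes to
every gene it annotates.  The **promoter** region is defined as
TSS1500 ∪ TSS200 ∪ 5'UTR ∪ 1stExon and the **gene body** as Body, the
standard convention for this platform; 3'UTR probes belong to neither
region subset.  A user-supplied exclusion list partitions probes into
the **methylation** class and the **S&C** class (potential SNP overlap
or cross-hybridization); "all probes" is their union.  Genes need ≥ 1
usable probe for single regression and ≥ 2 for the multivariate models;
constant probes are dropped with a log record.

## Models

All three models regress a gene's expression on its probes'
methylation.  R² is always the squared Pearson correlation between
predicted and observed values.  For in-sample OLS with an intercept
this equals 1 − SSE/SST; for shrunken fits and out-of-sample
predictions the two diverge, and the squared correlation is the
quantity reported throughout.

* **Single.**  Each CpG is regressed on its own; the per-probe p-value
  is the slope t-test and the probe with maximum R² represents the
  gene.  Ties break to the first probe in ascending-id order (probe
  order within a gene is always ascending id, for reproducibility).
* **Multiple.**  OLS with intercept on all probes.  Rank-deficient
  designs — including saturated ones with p ≥ n−1 — are fit with the
  minimum-norm least-squares solution and flagged rather than refused;
  saturated fits interpolate (R² = 1) and their overall F-test is
  reported as NaN.  Otherwise the overall p comes from
  F = (R²/d₁)/((1−R²)/d₂) with degrees of freedom taken from the
  numerical rank.  A gene is *significant* at α = 10⁻⁴ on this test.
* **Lasso.**  Predictors and response are standardized to unit
  variance; the penalty path is 100 geometric points from
  λ_max = max|X'y|/n down to 10⁻³·λ_max (the path depends only on the
  data, never on a seed; its top point is inflated by a relative 10⁻¹⁰
  so the all-zero solution there survives round-off).  The penalty is
  chosen by inner 10-fold CV minimizing mean squared error, ties going
  to the larger (sparser) penalty; `selection_rule="1se"` switches to
  the one-standard-error rule, which is markedly more conservative on
  null data (see "Null behaviour" below).  Coefficients are reported on
  the original predictor scale.  A fit is **valid** iff ≥ 1 coefficient
  is nonzero at the selected penalty.

### The path solver

The pipeline solves on the order of 10⁵ small penalized paths inside
nested cross-validation, so the coordinate descent runs in gram
(covariance) form — cost independent of n once X'X is built — compiled
with numba, with active-set iteration between full sweeps and warm
starts along the path.  The inner CV reuses the full gram via exact
rank-downdates per fold (training-fold centering included), instead of
rebuilding X'X ten times.  The solver matches
`sklearn.linear_model.lasso_path` to ~10⁻⁸ at tight tolerance and
reproduces `LassoCV`'s selected penalty on shared folds; both checks
are part of the test suite.  Default tolerance 10⁻⁵ (max coefficient
change on the standardized scale) with a 200-sweep budget per path
point keeps overparameterized p > n designs tractable.

## Cross-validation

Prediction R² (R².cv) uses repeated 5-fold CV with 10 repeats.  Per
repeat: a fresh random partition into five folds; each fold predicted
from a model fit on the other four; **one** squared correlation between
the pooled out-of-fold predictions and observed y; R².cv is the mean
over repeats (per-fold averaging is available via `pooled=False`).
Everything the model learns — penalty selection, standardization,
best-CpG choice under the `refit` strategy — is re-estimated inside
each training portion, so held-out data never leaks into a fit.

For the single-CpG model two strategies exist.  The default
(`max_per_cpg`) cross-validates every CpG separately and keeps the
maximum of the per-CpG mean R² — each CpG's predictions are
leakage-free, but the final maximum is taken over CV estimates and is
therefore optimistically selected.  The `refit` strategy instead
re-selects the best training-portion CpG inside every fold, which is
selection-free but no longer reports a single representative CpG.  Both
are exposed because either reading is defensible; `max_per_cpg` is the
default.

**A bias worth knowing about:** with pooled predictions, each fold's
intercept contains the training mean, which is anti-correlated with the
held-out fold's mean (when the overall mean is fixed, train mean =
−n_te/n_tr × test mean).  Under the null this inflates the pooled
squared correlation above the naive 1/(n−1) level: at n = 100 the null
mean of R².cv is ≈ 0.034, not 0.010 (verified against an independently
coded permutation oracle).  The calibration experiment accounts for
this by testing the max QQ departure against a Monte-Carlo band rather
than expecting the null CV distribution to match the Fisher reference
point-wise.

## Fisher-z null and intervals

With z = atanh(r) ~ N(0, 1/(n−3)) under no association, the q-quantile
of null R² is tanh(Φ⁻¹((1+q)/2)/√(n−3))², and the 95% interval for an
observed R² maps ±1.96/√(n−3) through tanh and squares it, clipping the
lower bound at 0 when the z-interval crosses zero.  QQ comparisons
match rank i of G genes to q = (i−0.5)/G and report the maximum of
observed − expected; `qq_null_band` provides the 99th percentile of
that statistic under simulated null draws.  The analytic quantile
agrees with 100,000 simulated correlations of independent normal pairs
at n = 100 to within 7×10⁻⁵ at the median and 99th percentile.

## Summaries

Model comparisons are restricted, per probe-set/region mode, to genes
with a **valid** LASSO model, so all models are counted over one gene
set.  Threshold tables count genes with R² strictly above 0.1 / 0.2 /
0.3; percentages are rounded half-away-from-zero to two decimals.
Nominal (uncorrected) per-CpG significance tallies use the minimum
per-probe p-value.  The probe-class comparison reports, per gene, the
R² from methylation probes, S&C probes and all probes, flags genes
whose all-probe R² leaves the Fisher CI of the methylation-only R², and
computes the cross-gene correlation between the two classes' R².
Genes lacking a valid model in a mode are reported missing, not zero.

## Synthetic cohorts

The generator emulates the structure of population array studies so
every stage is testable without downloads:

* **CpG correlation.**  Latent per-gene Gaussian with AR(1) correlation
  ρ between adjacent probes (default 0.5 — neighbouring CpGs are
  correlated, distant ones less so).  Observed values are the latent
  variable on the M scale or its base-2 logistic on the beta scale.
* **Genotype-like probes.**  A configurable fraction (default 0.29,
  the array-wide share of excluded probes) is replaced by three-cluster
  values at Hardy–Weinberg frequencies from a drawn MAF ∈ [0.05, 0.5],
  cluster separation δ = 1 on the latent scale plus N(0, 0.15) jitter —
  the categorical signature of SNP-affected probes.
* **Effects.**  Expression is y = Xβ + ε with β supported on a few
  causal probes (default 3), magnitudes U(0.5, 1.5), signs following
  the regional convention (promoter effects negative with probability
  0.8, body positive with probability 0.8).  ε is scaled so the
  population variance explained equals the gene's drawn target R²
  (exact on the M scale via the AR(1) covariance; via a 20,000-draw
  seeded Monte-Carlo under the logistic link on the beta scale).  The
  default target distribution is a 50/50 mixture of a point mass at 0
  and U(0, 0.9) — most genes weakly predictable, some strongly.
* **Dual independent effects.**  For the probe-class comparison the
  generator can plant methylation-driven and genotype-driven components
  with separate targets; the `balanced` assignment crosses presence/
  absence of the two classes in an exact 2×2 factorial over genes, so
  the planted effects are empirically orthogonal by construction.  A
  strictly disjoint two-group split would *not* produce a near-zero
  cross-mode correlation: pooling two groups with opposite means yields
  a structurally negative covariance, which is a property of that
  design, not of the biology being emulated.
* **Missingness** is completely at random at a configurable rate
  (default 0; 0.01 in the beta-scale preset), mimicking cohorts whose
  methylation matrices ship with missing entries.

What the generator does **not** emulate: array normalization artifacts,
batch effects, cell-type composition, twin relatedness, genomic probe
positions (probes-per-gene is uniform 3–60 by default, a stand-in
consistent with ~19 modelled CpGs per gene on this platform).  Passing
tests on these cohorts demonstrates the statistical machinery is
correct and calibrated, not that real tissues reach any particular
prediction accuracy.

## Validation experiments and problem sizes

Three seeded experiments (in `methylpred.experiments`, run by both the
test suite and `scripts/acceptance.py`) exercise the full stack:

* **Null calibration** — 1,000 all-null genes at n = 100 (probes per
  gene 3–20): the fraction of genes with LASSO R².cv > 0.3 must be
  ≤ 1%, and the QQ departure from the Fisher reference must stay inside
  its 99% Monte-Carlo band (300 simulations).
* **Recovery** — 50 genes at n = 500, p = 20, 3 causal probes, ρ = 0.3,
  planted R² = 0.5: the mean LASSO R².cv must land in [0.40, 0.55], the
  out-of-sample means must order lasso ≥ multiple ≥ single and the
  in-sample means multiple ≥ lasso ≥ single.
* **Independence** — 200 genes at n = 200 with balanced dual effects:
  the cross-mode R².cv correlation must lie within ±0.1 of 0.  This
  experiment uses 3 CV repeats (the correlation is an average over 200
  genes, so per-gene repeat noise is already well suppressed) and skips
  the validity filter, which would distort the factorial balance
  through selection.

These sizes keep a full validation run at a few minutes on one CPU
while leaving each assertion several standard errors of margin.

## Null behaviour of penalty selection

Minimizing CV-MSE (the default rule, glmnet's `lambda.min`) admits one
or two spurious predictors on roughly 35–50% of pure-noise genes — a
property shared by scikit-learn's `LassoCV` and glmnet itself, verified
against both.  The one-standard-error rule (`selection_rule="1se"`,
glmnet's default when extracting coefficients) keeps the all-zero model
on essentially all null genes and reproduces the regime in which most
genes lack a valid LASSO model.  Validity-based gene filtering is
therefore rule-dependent; the CV R² itself is much less sensitive,
since spurious predictors barely move out-of-sample predictions.

## Known limitations

* No covariate adjustment (age, sex, ancestry, cell composition) and no
  array normalization — inputs are assumed normalized upstream.
* Only the LASSO penalty; ridge / elastic-net / grouped penalties are
  out of scope.
* The promoter definition and the mean-collapse of duplicate expression
  rows are platform conventions, not inferred from data.
* The pooled-CV intercept bias above means null CV R² values are not
  Fisher-distributed; comparisons against the analytic null should go
  through the Monte-Carlo band, as the calibration experiment does.
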