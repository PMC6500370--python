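"""Generate a small synthetic methylation/expression cohort with known truth.

The generator emulates a population array study: per gene, a block of
adjacently correlated CpG probes (beta values through a logistic link),
a fraction of genotype-like probes (the S&C class), sparse causal effects
on expression, and missing values at random.  The printed table shows the
planted variance explained per gene — the ground truth every downstream
estimate can be compared against.
"""

from methylpred.simulate import GeneratorConfig, generate_dataset, planted_r2

config = GeneratorConfig(
    n_samples=120,
    n_genes=8,
    probes_per_gene=(5, 15),
    scale="beta",
    missing_rate=0.01,
    target_r2=((0.5, 0.0), (0.5, ("uniform", 0.2, 0.7))),
    seed=42,
)
paired, gene_map, classification, truth = generate_dataset(config)

print(f"expression matrix: {paired.expression.values.shape} (genes x samples)")
print(f"methylation matrix: {paired.methylation.values.shape} (probes x samples)")
print(f"missing methylation entries: {paired.methylation.n_missing}")
print(f"S&C (genotype-like) probes: {len(classification.probe_ids('s_and_c'))}")
print()
print(f"{'gene':8s} {'probes':>6s} {'causal':>6s} {'planted R2':>10s}")
for gene, gt in truth.genes.items():
    print(
        f"{gene:8s} {len(gt.probe_ids):6d} {len(gt.causal_probes):6d} "
        f"{planted_r2(truth, gene):10.3f}"
    )
print()
print("planted R2 is the population fraction of expression variance that")
print("the causal CpGs explain; 0 means the gene's expression is pure noise.")
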