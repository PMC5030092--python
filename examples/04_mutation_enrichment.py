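"""Covariate-matched bootstrap test for mutation enrichment in E2 genes.

Plants a 3-fold mutation preference for E2-induced genes, builds a control
set matched on replication timing and mean expression (studentized greedy
nearest-neighbour), and tests the difference in medians by pooled
resampling — the structural-variant/translocation flavour compares
z-scores of mutated vs matched genes, the simple-somatic flavour compares
log10 per-kilobase mutation rates of induced vs matched non-induced genes.
"""

from driptools import (
    EnrichmentConfig,
    SimulationConfig,
    run_enrichment,
    simulate_gene_table,
    simulate_mutations,
)

cfg = SimulationConfig(seed=42, mutation_enrichment_odds=3.0)
genes, _ = simulate_gene_table(cfg)
mutations = simulate_mutations(genes, cfg)
config = EnrichmentConfig(n_resamples=10_000, seed=42)

for mclass in ("structural_variant", "translocation", "simple_somatic"):
    res = run_enrichment(genes, mutations, mclass, config)
    print(f"{mclass:>18}: statistic={res.statistic:<17} "
          f"median test={res.median_test:+.3f} matched={res.median_matched:+.3f} "
          f"delta={res.delta_median:+.3f} p={res.pvalue:.2g} "
          f"(n={res.n_test} vs {res.n_matched})")

print("With a 3-fold planted preference all three classes show positive "
      "delta medians at the p-value floor; at odds 1 the deltas vanish and "
      "p-values spread uniformly.")
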