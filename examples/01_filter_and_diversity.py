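"""Filter a synthetic OTU table and compute its diversity diagnostics.

These diagnostics (mean inverse Simpson diversity and table sparsity) are
what motivates an ensemble approach to co-occurrence detection: moderately
diverse, half-zero tables defeat any single correlation measure.
"""

import commstable as cs

spec = cs.BlockSpec(n_samples=150, block_sizes=(8, 8),
                    n_background_otus=80, rho_within=0.7,
                    depth_range=(10_000, 20_000),
                    lognormal_mu_sd=(0.0, 3.0),  # wide spread -> rare OTUs
                    seed=42)
table, truth = cs.simulate_block_table(spec)
print(f"raw table: {table.shape[0]} samples x {table.shape[1]} OTUs")

table = cs.filter_low_quality(table, min_sample_depth=10_000,
                              min_otu_samples=2)
subset = cs.prevalence_filter(table, min_fraction=0.25)
print(f"after depth >= 10,000 and prevalence >= 25%: "
      f"{subset.shape[0]} x {subset.shape[1]}")

depth = min(10_000, int(subset.depths().min()))
inv = cs.alpha_diversity(subset, "inv_simpson", depth=depth, n_reps=10,
                         seed=0)
print(f"mean inverse Simpson diversity: {inv.mean():.1f} "
      "(effective number of equally abundant OTUs per sample)")
print(f"table sparsity: {cs.sparsity(subset):.2f} "
      "(fraction of zero cells)")
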