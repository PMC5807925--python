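# Methods

This note documents the models and procedures implemented in `commstable`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Pipeline overview

OTU count table → quality filter (sample depth ≥ 10,000; OTU in ≥ 2
samples) → prevalence subset (OTU in ≥ 25% of samples, computed on the
unrarefied table) → four co-occurrence edge tables (Pearson, Spearman,
SparCC, CoNet-style ensemble) → directional intersection across a p-value
sweep, scored by scale-free fit → negative edges stripped → Louvain
communities at a stability/significance-selected resolution → cross-dataset
comparison (shared-node normalised VI with a permutation null) and Jaccard
mapping into community-types.

Alpha diversity (Shannon, inverse Simpson) is computed as the mean over ten
rarefactions to a fixed depth (default 10,000), with rarefaction as exact
multivariate-hypergeometric subsampling (without replacement). Shannon uses
natural logs by default — consistent with the VI normalisation by ln N used
throughout — with the base configurable.

## Pearson / Spearman edges

Computed on relative-abundance tables over all C(D,2) pairs. Two-tailed
p-values use the t transform with n−2 degrees of freedom (the t
approximation is also used for Spearman; adequate at the sample sizes this
pipeline targets), then Bonferroni adjustment over the number of pairs.
Zero-variance OTUs produce sentinel edges (p = 1, direction 0) rather than
being dropped, so every method sees the identical pair universe and the
downstream intersection is well defined.

## SparCC

Re-implemented from the estimator's definition. Per run:

1. Fractions: one Dirichlet(counts + 1) posterior draw per sample (strictly
   positive, so all log-ratios exist). A deterministic mode
   (`fraction_mode="ml"`, (counts+1)/(total+D)) exists for exact tests.
2. Log-ratio variances t_ij from the covariance of log fractions
   (ddof = 1).
3. Basis variances from the sparsity-approximation linear system
   ((D−2)I + J)ω² = row-sums of t; negative solutions are floored at 1e-12
   with a warning and the affected OTUs flagged.
4. ρ_ij = (ω_i² + ω_j² − t_ij)/(2ω_iω_j), clipped to [−1, 1].
5. Iterative exclusion: up to 10 times, the off-diagonal pair with the
   largest |ρ| ≥ 0.1 is removed from the row-sum system (the pair, not the
   OTUs) and the system re-solved.
6. The final ρ is the elementwise median over 20 fraction draws.

Pseudo p-values: 100 null tables are formed by permuting each OTU's counts
independently across samples; p = (1 + #{|ρ_null| ≥ |ρ_obs|})/(B + 1). The
add-one estimator never returns 0 (reference implementations of this
procedure can), which keeps downstream −log p finite; with B = 100 the floor
is 1/101 ≈ 0.0099, deliberately below the pipeline's p < 0.01 edge
threshold by construction when B ≥ 100.

The sparsity approximation is an assumption, not a convenience: when a
large fraction of pairs is truly correlated the basis variances are
systematically distorted and within-block correlations biased downward.
The recovery benchmark therefore plants 4 blocks of 5 OTUs in D = 50
(≈ 3% of pairs correlated, squarely inside the assumption); the generator's
default table (4 × 12 blocks in 108 OTUs) is deliberately denser and shows
visible attenuation — that is a property of SparCC, reproduced faithfully.

## CoNet-style ensemble

Four measures: Pearson, Spearman, Bray–Curtis (Σ|u−v| / Σ(u+v)), and
symmetrised Kullback–Leibler between the two OTUs' sample profiles (each
rescaled to sum 1, pseudocount 1/(2n) added, renormalised; configurable).

**Candidate selection.** Pairs are ranked per measure toward co-presence
(high correlation / low distance) and toward exclusion; a common rank cutoff
is widened in lock-step until the pairs top-ranked in *all four* measures
number at least the targets (default 2,000 positive + 2,000 negative,
matching the regime of co-occurrence studies with ~10⁶ pairs). On the much
smaller synthetic tables used in tests the targets are scaled to the pair
universe; when the targets exceed it, all concordant pairs are returned with
a warning. A pair qualifying in both directions is assigned to the side that
ranks it better. Note that Bray–Curtis ranks "co-presence" by profile
similarity, which penalises correlated pairs of very different mean
abundance: tight targets therefore act as an abundance-similarity filter,
and recovery-oriented analyses should keep the targets liberal relative to
the expected signal.

**ReBoot.** For each candidate pair the two columns are permuted
independently and every sample's composition renormalised (only the pair's
fractions change: new denominator = rest + f_i′ + f_j′), so the null retains
purely compositional association. Two-sided p = (1 + #{|null − null mean| ≥
|obs − null mean|})/(N + 1); a degenerate (zero-variance) null yields p = 1.
Direction = sign(obs − null mean), inverted for the two distances.

**Bootstrap screen and merge.** The original tool's internal
bootstrap/permutation z-score machinery is not part of this package's
contract; the implemented screen is: a measure supports an edge when the
ReBoot null mean falls outside the central 95% interval of the measure's
observed score over 1,000 (default) sample bootstraps; an edge is dropped
only when no measure supports it, or when supporting measures disagree on
direction. The merged p is the *minimum* over supporting measures (the
"keep the minimum" merge, not textbook Simes), then BH-adjusted across
retained edges; the edge table reports the BH q as its p. This is a
faithful-to-description ensemble, not a bit-faithful port.

## Network construction

An edge enters the intersection network iff it is present in all method
tables with the same nonzero direction and p strictly below the threshold.
Thresholds swept: 0.05, then 10⁻²…10⁻⁸ (8 values). Note the ReBoot and
pseudo p floors (1/(N+1)) mean the ensemble methods cannot pass thresholds
below their floor — sweeps on reduced permutation counts go empty early, as
expected.

Scale-free fit follows the binned log–log regression convention: degrees in
10 equal-width bins, per-bin mean degree k̄ and node fraction p(k̄),
regression of log₁₀ p on log₁₀ k̄; reported R² and signed slope; a single
occupied bin yields a NaN sentinel. Mean path length averages over connected
node pairs only (the networks need not be connected); mean clustering
averages local coefficients with degree-<2 nodes contributing 0; nodes of
degree 0 are never part of a network (an OTU exists in a network only via an
edge).

## Community detection

Unweighted Newman–Girvan modularity with resolution γ (the networks are
unweighted after intersection). Louvain is the seeded greedy two-phase
algorithm (networkx's implementation behind this package's surface);
community ids are relabelled 1..K by descending size for determinism.
Degree-matched null graphs: Havel–Hakimi realisation followed by 10×E seeded
double-edge swaps (count configurable). The γ sweep (default 0.1–1.0 in 0.01
steps, 91 values) reports per γ the stability (mean pairwise 1 − VI/ln N
over 25 runs), real and null modularity (one run on each of 100 random
graphs — the same 100 graphs reused across γ), and mean community count.
`choose_gamma` automates the selection rule: the most stable γ whose real
modularity exceeds the null mean by ≥ 2 null standard deviations. The final
partition is the best of 100 runs (run k seeded with seed + k; ties go to
the earliest run).

## Cross-dataset comparison

VI = H(A) + H(B) − 2I(A;B) with natural logs, computed over the OTUs shared
by the two partitions, normalised by ln(shared count) — each pairwise
comparison is treated as a self-contained universe, which is the operative
network when two different node sets are compared. The permutation null
shuffles which node carries which label *within each partition's full node
universe* (community sizes preserved) and recompares on the shared set;
observed similarity, null mean/sd/max are reported.

Communities are matched across datasets by Jaccard of their OTU sets,
strictly above 0.25. Matches are grouped into connected components; a
component containing exactly one community from every dataset becomes a
community-type, labelled from a fixed 30-colour vocabulary in order of
descending mean Jaccard (deterministic labelling). A community matching two
or more communities in the same other dataset voids type formation for its
component, with a warning — the 0.25 threshold is chosen in practice
precisely so this does not happen.

## Community profiling

Community abundance = summed member counts / sample total (OTUs outside the
network still count toward the denominator). Associations: OLS of
log₁₀(abundance + 10⁻⁶) on BMI + age + sex + sequencing depth, listwise
deletion of missing covariates, sex as a categorical with "unknown" as its
own level; BMI and age coefficients extracted with two-tailed p, BH-FDR per
phenotype across the non-constant communities (constant ones are excluded
and reported). Covariates enter in raw units. Mean pairwise identity uses
global (Needleman–Wunsch) affine-gap alignment at match +1 / mismatch −1 /
gap open −2 / gap extend −1; identity = identical columns / alignment length
including gap columns (denominator configurable to shorter-sequence length);
singleton communities yield NaN.

## Synthetic data

`BlockSpec` defines the generative model: latent log-abundances drawn from a
multivariate normal whose correlation matrix is block-diagonal (ρ_within in
planted blocks, 0 elsewhere; per-OTU baseline means N(0, 1) by default),
exponentiated, normalised per sample, and converted to counts by a
multinomial draw at a depth uniform in 20,000–60,000. The latent Gaussian
copula was chosen over a Dirichlet-multinomial precisely because it gives a
known pairwise correlation target for recovery tests; the truth object
carries the latent draws so planted correlations can be verified exactly
(count-scale correlations are attenuated by multinomial noise, roughly 0.64
observed for a 0.7 latent at the default depths). Replicate cohorts share
the latent structure (means, correlation) and differ by independent OTU
dropout masks and sampling noise. Reference defaults: 400 samples, four
12-OTU blocks at ρ = 0.7, 60 background OTUs, 10% dropout for replicates.

What the generator does **not** emulate: real zero-inflation beyond what the
log-normal/multinomial induces (the default tables are much denser than real
16S tables; a wide `lognormal_mu_sd` adds rare taxa but the zero process is
still purely sampling), phylogenetic correlation between taxa, batch
effects, or uneven library preparation. Passing tests therefore demonstrate
correctness of the estimators and pipeline under a known truth — not that
any particular real dataset satisfies the estimators' assumptions.

Graph fixtures: stochastic-block-model draws (with the true partition), and
power-law degree sequences built deterministically by rounding expected
degree counts (so the binned log–log curve lies on the target slope) and
realised by Havel–Hakimi plus seeded double-edge swaps.

## Problem sizes and reproducibility

All randomness flows through explicit integer seeds (numpy SeedSequence;
derived seeds kept below 2³¹), and every generator and estimator is
bit-reproducible per seed. The test and verification workloads use
desk-scale problem sizes chosen to keep each property measurable with
margin: SparCC recovery at D = 50, n = 500 over 10 seeds; ensemble null
calibration at D = 25, n = 100 with 200 ReBoot permutations over 10 seeds;
the three-cohort replication at the generator defaults with 999 ReBoot
permutations (p floor 1/1000, comfortably below the 0.01 edge threshold),
300 + 300 candidate targets (≈ 10% of the 5,778-pair universe, mirroring a
liberal initial cut), a reduced γ grid (0.2–1.0 step 0.2, 10 runs, 20 random
graphs), and a 1,000-permutation VI null.

## Known limitations

* The ensemble's CoNet component reproduces the described procedure, not the
  original tool's exact p-value machinery; absolute q-values differ from
  CoNet's even though the qualitative behaviour (compositionality-aware
  nulls, min-merge, BH) matches.
* The p-value floors of the permutation-based methods quantise the low end
  of the sweep; thresholds below the floor are only meaningful for the
  analytic methods.
* `select_initial_thresholds` couples candidate edges to Bray–Curtis profile
  similarity (see above); this mirrors the upstream design but means tight
  targets are not a neutral significance filter.
* Heritability modelling of twin data and upstream sequence processing (OTU
  clustering, taxonomy assignment, tree building) are out of scope; the
  pipeline starts at a count table.
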