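# Methods

This note documents the statistical procedures implemented in `comirnet`,
the tunable parameters and their defaults, the synthetic-data model used
for validation, and the numerical and design choices made where the
methodology left room.

## Systematic-effect adjustment

Expression intensities (log2 scale) and trait measurements are adjusted by
per-variable linear regression on a common design: sex and genotype as
categorical fixed effects, sire and slaughter day as grouping factors,
carcass weight as a centered numeric covariate. Two modes:

* `fixed_ols` (default): every categorical term is dummy-coded
  (reference-level) and residuals are ordinary least squares. Residuals
  are exactly orthogonal to the design column space, so the adjustment is
  idempotent and directly testable (orthogonality tolerance 1e−8). A
  rank-deficient design is rejected with the aliased columns named (via
  pivoted QR).
* `reml_one_random`: one grouping factor (configurable, default sire)
  enters as a random intercept fitted by restricted maximum likelihood
  (statsmodels MixedLM); residuals subtract both the fixed-effect fit and
  the predicted random effects. When the variance component degenerates to
  zero and the optimizer fails, the probe falls back to the fixed-effects
  limit (group dummies), with a warning. At the package's working scale
  both modes give nearly identical residuals; `fixed_ols` is the default
  because its correctness is exactly checkable.

Phenotypes are adjusted trait-by-trait with case-wise deletion of missing
values; the same design is used for expression and phenotypes.

Between-chip **quantile normalization** (applied to miRNA arrays by
default) forces every sample column onto the per-rank column-mean
distribution; tied values receive the mean of the reference values at the
ranks the tied group occupies, which preserves within-sample rank order
and makes permuted columns map to permuted identical outputs.

**Outlier screening** clusters samples by average-linkage on Euclidean
distances and flags samples whose first merge into the tree occurs above
`median + cut_z × MAD` of all first-merge heights (MAD scaled by 1.4826 so
`cut_z` is on a σ-equivalent scale; default `cut_z = 4`). The screen is
applied once, not iterated.

## Co-expression network

* **Correlation**: Pearson, pairwise-complete if missing values are
  present; zero-variance probes are rejected by name.
* **Adjacency**: unsigned `a_ij = |r_ij|^β` by default; a signed variant
  `((1+r)/2)^β` is available for sensitivity analysis. The unsigned form
  is the field's default and treats strong negative co-expression as
  connectivity.
* **Soft-threshold selection**: candidate powers β = 1…12. For each β,
  connectivities `k_i = Σ_{u≠i} a_iu` are split into 10 equal-count bins;
  each non-empty bin contributes (log10 mean k, log10 frequency *density*
  = count/(n·width)), and R² comes from the OLS fit of that log–log
  relationship. The selected β is the smallest with R² above the target
  (default 0.9); if none qualifies, the β with maximal R² is used and the
  scan is flagged. Density rather than raw bin frequency is used because
  equal-count bins make raw frequencies constant by construction; the grid
  stops at 12 because rank-1 block data shows monotonically creeping R²
  at large β while the network itself degrades — powers ≤ 12 preserve
  module recovery across the validation suite.
* **Topological overlap**: `ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 −
  a_ij)` with `l_ij = Σ_{u∉{i,j}} a_iu a_uj` and `k_i = Σ_{u≠i} a_iu` —
  the convention under which a clique attains ω = 1 exactly. The
  implementation is a matrix product with the self-terms subtracted and is
  tested to 1e−12 against a literal triple-loop evaluation.
* **Module detection**: average-linkage clustering of `d = 1 − ω` with a
  constant-height cut. By default the cut height is placed automatically
  at the midpoint of the largest gap in the sorted merge heights (searched
  above the 25% height quantile): modular data with an unstructured
  background produces a wide empty band between within-module merges and
  the near-1 background merges, and cutting inside that band separates
  modules from grey robustly. A fixed-height quantile rule was tried first
  and discarded — background merges crowd the top of the dendrogram and a
  high fixed quantile lands above the band, merging everything. Clusters
  below the minimum size (30 for mRNA, 10 for miRNA networks) dissolve
  into grey. Dynamic tree cutting, used by the reference tooling, is
  deliberately replaced by this simpler deterministic rule; it is
  sufficient for planted-structure recovery and makes runs exactly
  reproducible.
* **Eigengenes**: member profiles are standardized per probe; the
  eigengene is the leading right singular vector across samples (unit
  norm), signed to correlate non-negatively with the members' average
  profile; variance explained is the leading squared singular value over
  the total.
* **Merging**: while any pair of module eigengenes has dissimilarity
  `1 − cor` below the threshold (default 0.2), the closest pair is merged
  (larger module keeps its identity; ties break by label order), the
  eigengene is recomputed, and the loop repeats. Final labels follow a
  fixed color sequence in decreasing module size; labels carry no
  semantics.
* **MM / GS**: module membership is the signed correlation of each probe
  with each eigengene; gene significance is the absolute correlation of
  each probe with each trait, pairwise-complete.

## Module–trait association

Each eigengene × trait cell reports Pearson r, the two-sided p from
`t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of freedom, and the exact n
used (missingness makes n vary by trait). |r| = 1 underflows; p is clamped
to the smallest positive double rather than reported as zero. No
multiple-testing correction is applied at this stage — the full matrix is
emitted so users can apply their own. Trait-associated modules are those
with any cell below α (default 0.05); each module is also reported once
with its best cell.

## miRNA–mRNA pair integration

All miRNA-probe × mRNA-probe pairs are correlated on residuals (each pair
with its own pairwise-complete n). The total test count m always reflects
the full probe grid, even when only a subset of correlations is
materialized, so FDR control refers to the full family of tests.

**q-values**: `q_i = min_{p_j ≥ p_i} π0·m·p_j/rank(p_j)`, capped at 1.
In `storey` mode π0 is estimated on a λ grid (default 0.05…0.95, step
0.05): `π0(λ) = #{p > λ}/(m(1−λ))` is made monotone non-increasing by a
running minimum along increasing λ, and the median of the monotone
sequence is taken, clipped to [1/m, 1]. This deterministic monotone-median
rule replaces the usual spline smoother, which introduces fitting
ambiguity without changing the estimator's target; with π0 fixed at 1 the
estimator reduces exactly to Benjamini–Hochberg (`bh` mode). Joint FDR
control over all pairs (not per sign) is used.

**The regulatory-link filter**: negative pairs (r < 0, q ≤ 0.1) whose mRNA
sits in a trait-associated, non-grey module form the candidate set
(criteria 1 ∧ 2); prediction evidence (criterion 3, either method) marks
the confirmed subset. miRNA probes are collapsed to families for
reporting — the family row carries the most negative probe-level pair and
the union of prediction flags — with all probe-level rows retained in a
companion table.

## Target prediction

* **Seed sites**: with the miRNA written 5'→3', a site on the UTR is the
  reverse complement of positions 2–8 (7mer-m8), the reverse complement of
  2–7 followed by A (7mer-A1), or both (8mer). Each seed-match locus is
  reported once with the strongest applicable class; G:U is not accepted
  in seed matches. Coordinates are 0-based half-open; only the given
  strand is scanned.
* **Duplex energy**: a dynamic program over intermolecular base pairing
  only. States are (miRNA index, UTR index) end pairs; transitions are
  stacks (both indices advance by one; energy from the stack table) or
  bulge/internal loops of at most `max_loop` unpaired nucleotides per side
  (default 4) at `loop_penalty` per nucleotide (default +0.5 kcal/mol).
  The energy model is a deliberately small stack-class table — a stack is
  scored by its weakest member: GU-containing −1.0, AU-containing −2.0,
  pure GC −3.0 kcal/mol — not a full nearest-neighbor parameterization.
  Correctness is asserted against exhaustive enumeration over the same
  transition grammar on short sequences. Up to `hits_per_target`
  non-overlapping windows are returned (default 1), with deterministic
  tie-breaks (leftmost UTR start, then shortest duplex).
* **Energy cutoff**: `duplex_hit ⇔ mfe ≤ cutoff`. Because the stack-class
  model is not on the scale of full thermodynamic parameters, the default
  cutoff is calibrated to the distribution of best duplex energies between
  *random* sequences at typical lengths (22-nt miRNA vs 120–220-nt UTR):
  −28.5 kcal/mol sits at the ~1% tail of that null distribution, mirroring
  the stringency that a −25 kcal/mol threshold has under full
  nearest-neighbor parameters (where it is a rare-event threshold, not a
  5% one). Users supplying a different energy model should recalibrate the
  cutoff against the same null construction.
* In the end-to-end pipeline, prediction runs only on candidate pairs that
  already pass the expression-based criteria — prediction is confirmatory,
  so the full sequence grid would change nothing downstream.

## Enrichment

Per-term significance is the one-sided hypergeometric upper tail of the
overlap between a module's genes and the term, both restricted to the
background (default: all analyzed probes, not the genome). Percent count
is overlap over the module's annotated genes × 100. Terms are clustered by
Cohen's kappa between their binary gene-membership vectors over the
background, single linkage at kappa ≥ 0.35 (i.e. connected components of
the kappa graph); each cluster scores `ES = −log10` of the geometric mean
of its members' unadjusted p-values. This deterministic clustering stands
in for interactive fuzzy annotation-clustering heuristics with the same
inputs and outputs. A permutation utility draws random gene sets of
matched size and returns their best term p-values, giving an empirical
null for judging observed enrichment.

## Synthetic data model

The generator's defaults define the package's validation conditions: 600
genes, 60 miRNAs, 120 samples, 5 modules of 60–100 genes (desk scale —
structurally faithful to a ~200-animal, ~11k-probe study but far smaller).

* Each module is rank-1: gene = loading × factor + noise, loadings
  U(0.7, 0.95), noise sd 0.6, factors i.i.d. standard normal per sample.
  These choices give within-module gene–gene correlations around 0.6 —
  strong but realistic co-expression. Background genes are pure noise with
  matched total variance; probe baselines sit at log2-intensity ≈ 7 ± 1.
* Each module drives two traits with effect sizes U(0.2, 0.35) — the
  magnitude of organismal-trait correlations at this scale; the trait's
  noise is scaled so the population correlation with the factor equals the
  target exactly. 2% of phenotype values are missing at random to exercise
  pairwise-complete code paths.
* Half the miRNAs are regulators, grouped into 10 families of 3 sharing
  positions 2–8 of the mature sequence; each family loads negatively on
  one module's factor (regulator–target correlations ≈ −0.6) and targets
  10 distinct genes in that module; each target UTR (length U{120..220})
  carries the family's exact 8mer site at a random position, with flanks
  neutralized so the planted class is exact. Every planted edge is thus
  jointly recoverable by construction: negative population correlation
  AND a seed site.
* Nuisance effects (sex, 3-level genotype, 8 sires, 6 slaughter days,
  carcass weight) enter additively with per-gene level effects (sd
  0.2–0.3), so the fixed-effects adjustment is exactly correctly
  specified; an optional quadratic carcass-weight term tests robustness to
  misspecification.
* One annotation term per module covers ~70% of its genes; random
  background terms (20–60 genes) provide nulls.

All randomness flows from one seeded generator (NumPy PCG64); identical
parameters and seed give byte-identical outputs.

**What the generator does not emulate**: probe-level hybridization
physics, batch/array artifacts beyond additive chip effects, correlated or
hierarchical module structure (modules are mutually orthogonal rank-1
factors), non-canonical or conserved target sites, UTRs at realistic
(kilobase) lengths, and realistic annotation redundancy. Passing the
recovery suite therefore demonstrates correctness of the inference chain
under its own generative assumptions, not performance on real arrays.

## Validation problem sizes

The test suite and the acceptance script run the generator at its default
desk scale: module recovery and end-to-end edge recovery use ten seeded
replicates of the 600-gene configuration; oracle comparisons use 100
random adjacencies (n ≤ 20) for the TOM, 150 short sequence pairs for the
duplex DP, 1,000 random pairs for the seed scanner, and 1,000 random
p-value lists for the q-value machinery. Moment checks on the generator
use 2,000 samples.

## Known limitations

* The constant-height gap cut assumes a visible separation band in the
  dendrogram; on data with nested or overlapping modules, dynamic tree
  cutting would be preferable.
* The REML mode supports exactly one random intercept; multi-component
  designs are approximated by the fixed-effects mode.
* The energy model's absolute scale is not thermodynamic; duplex energies
  are comparable within a model only, and the cutoff must be recalibrated
  if the model changes.
* Family collapsing reports extremal statistics, which are biased
  anticonservative if read as single-pair estimates; probe-level rows are
  retained for that reason.
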