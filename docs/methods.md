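# Methods

This note records the model, the defaults and why they are what they are,
what the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Model

Bulk expression of gene *g* in sample *s* is treated as an additive mixture
of latent per-sample cell-type signals:

    e_gs = Σ_c α_gc · x_cs + β_g · x_0s + ε_gs

`x_c` is cell type *c*'s activity profile across samples, `x_0` a shared
residual factor (technical and non-cell-type biology), `α_gc` and `β_g`
non-negative gene loadings, `ε` noise. Nothing in the pipeline estimates
this model directly; it motivates two operational identities:

- genes dominated by the same `x_c` cluster into one co-expression module,
  detectable by marker enrichment;
- within such a module, `x_c` is (approximately) the first principal
  component of the module's expression submatrix, so deleting PC1 and
  rebuilding the matrix removes that cell type's contribution while the
  secondary loadings of dual-loading genes survive and re-cluster.

## Network construction

- **Soft power.** Smallest integer in 1..30 whose signed scale-free fit R²
  (log10 binned-connectivity frequency on log10 binned connectivity, 10
  equal-width bins, sign-corrected for slope) reaches 0.80; otherwise the
  maximizing power, with a warning. The 0.80 threshold and 10 bins are
  community convention. Caveat: raising noise correlations to a high power
  manufactures a heavy connectivity tail, so a pure-noise matrix can pass
  the R² criterion at high powers; the fit index alone is not a noise
  detector, which is why the selection is also covered by an
  independent-oracle test rather than an "it must warn on noise" test.
- **Adjacency / TOM.** Unsigned adjacency `|cor|^β` by default
  (`signed_hybrid` optional), Pearson throughout. Standard unsigned TOM,
  `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, unit diagonal.
- **Clustering.** Average linkage on `1 − TOM`. The dendrogram is cut at
  the height that maximizes the number of clusters of size ≥ 100 (ties go
  to the lower height); candidate cuts are taken after *all* merges at a
  given height, so tied merge heights cannot yield partial partitions.
  Sub-threshold clusters become `unassigned`.
- **k-means refinement.** Up to 50 passes; centroids are module
  eigengenes; every gene (including unassigned) moves to the module whose
  eigengene it correlates with most strongly in absolute value, subject to
  a floor of |r| ≥ 0.3 (below it the gene stays/becomes unassigned — the
  floor keeps weakly connected background genes from inflating modules and
  is configurable). Early stop when no gene moves; modules ending below
  the minimum size dissolve.
- **Eigengenes.** First right singular vector of the row-standardized
  (z-scored, ddof 1) module submatrix, scaled to unit variance, sign
  anchored so its mean correlation with member rows is non-negative.

## Enrichment

One-sided Fisher's exact test per (module, marker set), background = the
full network gene pool, markers intersected with the background first.
Bonferroni over the whole table, then an OLS of −log10(p_Bonferroni) on
module size; a call requires p_Bonferroni < 0.05 **and** a positive
residual (beyond 1e-9, a float-noise guard). The order — correct first,
regress second — mirrors the procedure the adjustment was designed to
reproduce. With fewer than 3 tests the regression is skipped; with
constant module sizes the slope is dropped and residuals are centered
values. A module enriched for several cell types keeps only the smallest
corrected p (ties: larger residual, then lexicographic name, logged);
the marginal signal is discarded.

## Signal removal

Per treated module: rows gene-centered (not unit-scaled — reconstruction
must return to expression units; scaling is an option), SVD, k = smallest
component count reaching 90% cumulative variance, reconstruction from
components 2..k plus gene means. Both PC1 and the beyond-90% tail are
removed by construction. A rank-1 module (k = 1) collapses to constant
per-gene means with a warning: those genes are inert in the secondary
network. Soft power is re-selected per secondary matrix — the corrected
matrices differ materially from the primary one.

## Validation statistics

- **Preservation Z-summary** is a deliberate two-statistic simplification
  of the WGCNA modulePreservation battery: density (mean |cor| among
  module genes in the test data) and connectivity (Spearman agreement of
  intramodular connectivity between reference and test), each standardized
  against ≥ 100 random same-size gene sets; Z-summary is their mean. The
  published thresholds (2 weak, 10 strong) keep their semantics, but the
  statistic is *not* numerically WGCNA's. In the synthetic world a
  "replicate" shares gene loadings and redraws factors and noise; because
  the entire replicate then preserves structure, the connectivity null is
  itself preserved and the density component carries the planted-module
  signal. Null standard deviations are floored at 1e-12 to keep Z finite.
- **Specificity matrices.** Purified-profile variant: average replicates
  per cell type, log2(x+1), center/scale the whole matrix, TRUE above the
  global mean (log before scale; the reverse order is a config away).
  Single-cell variant: drop all-zero cells, TRUE where the cell-type mean
  is ≥ 3 × the gene's overall mean (inclusive), genes with zero overall
  mean FALSE. The "overall mean" is per gene across all retained cells —
  the self-consistent reading of an ambiguous rule, noted for users.
  Note an arithmetic consequence: with T equally sized cell types the
  fold change against the overall mean cannot exceed T, so markers must
  be near-silent off-type to clear a threshold of 3.
- **Bootstrap enrichment.** Observed mean specificity of the target in one
  column vs. equally sized gene lists resampled without replacement
  within a list; p = (1 + #{null ≥ obs}) / (n_boot + 1), so p ∈ (0, 1]
  and the minimum is 1/(n_boot+1). Seeded; the resampling is vectorized
  when memory allows and loops otherwise, with identical distribution.
- **Phenotype enrichment.** coverage = |module ∩ term| / |module|, kept at
  ≥ 2%; fold change = coverage / background rate of the term.

## Synthetic generator

Defaults are the documented scenario: 150 samples; four cell types ×
300 genes (60 markers each); 40 dual-loading genes per disjoint adjacent
type pair (2 pairs → 80 genes; the total gene count pins this pairing
down); 800 background genes; primary loading |N(1.0, 0.1)|, secondary
|N(0.6, 0.1)|, shared-factor loading |N(0.5, 0.1)|, noise sd 1.0. The
last two are this package's choices (nothing pins them): β ≈ 0.5 gives
background genes a common factor too weak to form a module of their own
but strong enough to keep them realistically correlated (within-module
|r| ≈ 0.55 vs background |r| ≈ 0.2), and noise sd 1.0 puts module
detection in a comfortably non-trivial regime. Latent factors are
independent standard normals — the additive model is unconstrained, and
independence makes the ground truth unambiguous. Loadings can be reused
across draws (`simulate_bulk(cfg, loadings=...)`) to create independent
replicates of the same modules for preservation analysis.

What the generator does **not** emulate: count noise (negative binomial),
library-size and compositional effects, correlated cell-type abundances,
batch structure. A green recovery test therefore establishes that the
pipeline implements its own algebra correctly and that the stated-world
signal/noise regime is recoverable — not that real-tissue effect sizes
would be.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1]; constant gene rows are a hard error
  pointing at `preprocess.drop_zero_variance`.
- Zero-division guards: TOM cells with non-positive denominators (only
  possible in degenerate all-one adjacencies) are set to 1; underflowed
  p-values are floored at 1e-300 before log10.
- Residualization solves one least-squares system for all genes at once;
  collinear covariate columns are detected by rank and named by projecting
  each column on its predecessors.
- Categorical covariates are treatment-coded with the first level dropped.
- The permutation null of the preservation statistic samples from the
  lexicographically sorted shared gene list, making results invariant to
  input gene/sample order at fixed seed.
- Everything downstream of a fixed config and seed is deterministic; the
  run manifest (sorted-key JSON, fixed float formats, no timestamps) is
  byte-identical across reruns.

## Known limitations

- No block-wise approximation: matrices beyond ~30k genes will be slow and
  memory-hungry (dense TOM).
- Batch correction and surrogate-variable analysis are out of scope; the
  tool expects pre-corrected input and only regresses user-listed
  covariates.
- The preservation statistic is a simplification (see above); don't compare
  its absolute values against WGCNA's beyond the 2/10 semantics.
- One enriched cell type per module is enforced, matching the observation
  that multi-type enrichments are rare and marginal; tissues where that
  assumption fails would need the rule relaxed.
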