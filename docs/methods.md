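# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic data does and does not emulate, and the
numerical decisions made where the design was genuinely open.

## Microwell doublet model

Cells loaded by limited dilution onto a microwell array follow Poisson
occupancy with λ = N/W (loaded cells over wells). Conditional on a well
being occupied, the probability it holds two or more cells is
[1 − (1+λ)e^(−λ)] / (1 − e^(−λ)). With k sample tags assigned uniformly and
independently, a pair of co-captured cells is detectable (two distinct
tags) with probability (k−1)/k, giving the headline fraction

    D(λ, k) = [1 − (1+λ)e^(−λ)] / (1 − e^(−λ)) · (k−1)/k.

This is the quantity used to set the doublet quantile of the barcode
ranking, and at the reference capture (λ = 0.1, k = 3) it evaluates to
3.28% (3 s.f.).

**Truncation and the exact form.** The (k−1)/k factor is exact only for
wells with exactly two cells. An m-cell well is undetectable only when all
m cells drew one tag (probability k^(1−m)), so the full model is

    D_exact = [1 − (1+λ)e^(−λ) − k e^(−λ)(e^(λ/k) − 1 − λ/k)] / (1 − e^(−λ)).

At λ = 0.1 the two differ by about 1% relative (0.03278 vs 0.03314); by
λ = 1 the gap is large (0.209 vs 0.245 at k = 2). The brute-force
simulator `synth.simulate_microwells` estimates D_exact, and the test
suite compares simulation to the exact form within three binomial standard
errors, plus the algebraic bound 0 ≤ D_exact − D ≤ P(≥3 cells | occupied)
for the truncated form. D (not D_exact) is the ranking quantile because it
is the published convention for this capture regime.

**k is an input.** The loaded-cell and well numbers are properties of the
instrument run; the number of tags is a property of the experiment design.
The analysis drivers use k = 3, which reproduces the 3.28% quantile at
λ = 0.1; it is a model parameter, not a constant.

## Tag assignment

Raw tag×barcode counts are normalized by scaling each tag row to the
minimum positive row total (equalizing tag depth), each barcode is scored
by log₂((c₁+1)/(c₂+1)) of its two largest normalized counts, barcodes are
sorted ascending by (score, total, barcode id), the first
ceil(D · n_scored) are labelled doublets, all-zero barcodes are labelled
not-detected, and the remainder get their top tag.

Choices the procedure does not pin down by itself:

* **Pseudocount 1** keeps the score finite when the second count is zero
  and preserves ordering. A side effect is that exact scale invariance of
  the *labels* cannot hold: multiplying all counts by a perturbs
  log₂((ac₁+1)/(ac₂+1)) by O(1/c), which can swap barcodes whose scores are
  near-tied exactly at the doublet cutoff. Top-tag assignment is exactly
  scale-invariant; the tests assert invariance in that precise form.
* **ceil()** converts the fraction to a count; ties broken by total
  normalized count then barcode id, making the call deterministic.
* Which barcodes are "valid" is the caller's concern (in practice, the
  barcode list of the gene-expression matrix); the demultiplexer never
  calls cells from raw reads.

## QC and normalization

Droplet-style counts: cells with fewer than 500 detected genes (drivers
use 100 against the small 300-gene simulated panel) or a mitochondrial
read fraction strictly greater than 0.4 are removed first; genes detected
in fewer than 5 surviving cells are removed second. The order matters at
the margin and is fixed: cell filters, then the gene filter. Mitochondrial
genes come from a caller-supplied list, falling back to the "mt-" prefix
convention.

Plate-based FPKM: cells with fewer than 3,000 detected (strictly positive)
genes are removed; the co-expression branch keeps genes at FPKM ≥ 5
(inclusive) in at least 5 cells (inclusive). All boundary comparisons are
implemented with exactly this strictness and covered by boundary-value
tests.

Normalization is ln(count / cell total × 10⁶ + 1). Variable genes use the
de-logged mean ln(mean(eˣ−1)+1) and dispersion ln(var/mean), 20
equal-frequency mean bins, within-bin z-scoring, and the gates
0.1 < mean < ∞, z > 0.5; a bin with a single gene gets z = 0. Scaling
regresses each gene on a per-cell depth covariate (OLS with intercept) and
standardizes residuals to mean 0, sample SD 1; residual SDs that are float
noise relative to the gene's own spread (perfect fits) are treated as zero
variance and the row set to 0.

## PCA, PC significance, clustering, markers

PCA is the SVD of the centered cell×gene scaled matrix, deterministic up
to a fixed sign convention (largest-|loading| entry positive). `n_pcs` is
truncated at matrix rank with a warning.

PC significance is a permutation ("jackstraw" style) test: per replicate,
a random 1% of genes (5% in the small-fixture tests and drivers) have
their cell order permuted, PCA is recomputed, and the permuted genes'
absolute loadings pool into a per-PC null; each PC's p-value is a
one-sided Mann–Whitney comparison of observed |loadings| against that
null. On pure-noise matrices the significant-PC count stays near
α·n_PCs (calibration is tested). The exact statistic and aggregation are
this package's choices; only the replicate count (100) and threshold
(p ≤ 0.05) are fixed by convention.

Clustering builds a k-nearest-neighbor graph (k = 20, Euclidean, cells in
significant-PC space), re-weights edges by the Jaccard overlap of
neighborhoods (pruned below 1/15), and runs Louvain modularity
optimization (networkx, seeded) at the chosen resolution (1.5 default, 2
for sub-clustering). Labels are relabelled deterministically by decreasing
cluster size. An all-identical-coordinates input is returned as a single
cluster rather than handed to the graph machinery.

Markers are one-vs-rest Wilcoxon rank-sum tests per gene, gated by
expression in ≥ 10% of in-cluster cells and natural-log fold-change
ln((mean(eˣ−1)_in+1)/(mean(eˣ−1)_out+1)) ≥ 0.25, positive direction only.
**Bonferroni family:** the correction multiplies by n_genes ×
n_cluster_comparisons — the full family of hypotheses examined — not by
the handful of genes that pass the gates. The fold-change gate selects for
extreme observed differences, so correcting only over gated genes is
anti-conservative (shuffled-label data then yields spurious "significant"
markers at well above the nominal rate; with the family-wide correction
the null calibration test holds). Clusters with fewer than 3 cells are
skipped with a warning.

## Co-expression modules

Signed adjacency a_ij = ((1+r_ij)/2)^β with Pearson r and β = 12 (the
standard signed-network default; the analysis convention fixes "signed"
but not the power). Topological overlap is computed from the adjacency
with zeroed diagonal; modules are average-linkage clusters of 1 − TOM cut
statically at height 0.99, minimum size 30; undersized clusters are left
unassigned (label 0). The static cut is a deliberate simplification of
dynamic tree cutting: it is deterministic and sufficient for the
module-recovery guarantees tested here, but it will merge or drop modules
that a dynamic cut would resolve, so the number of modules on real data is
not a contract of this implementation.

The module eigengene is the first principal component of the module's
genes standardized across cells, scaled to unit variance and sign-oriented
to correlate positively with the module's mean standardized profile. Mean
module expression is exposed as an alternative summary.

Module ranking fits a bagged ensemble of decision trees (1,000 trees,
√m candidate features per split) classifying each cell's experimental
group from the eigengenes. Importance is the permutation mean decrease in
accuracy: per tree, out-of-bag accuracy minus OOB accuracy after shuffling
one eigengene, averaged over trees. The ensemble is hand-assembled from
scikit-learn decision trees because per-tree OOB sample identities —
required for this importance — are not exposed by the stock forest.
All randomness flows from the single seed argument.

## Trajectory and composition

Pseudotime: cluster centroids in significant-PC space, Euclidean minimum
spanning tree, rooted at an explicit start cluster (a helper picks the
cluster most enriched for a designated reference condition, mirroring how
a biologist roots the trajectory where control cells sit). Each cell is
projected onto its nearest parent→child segment; pseudotime is arc length
from the root to the projection, shifted so the minimum is 0. Lineages are
root→leaf paths. A single-cluster input falls back to arc length along the
cells' first principal direction. The construction is purely Euclidean,
hence invariant under rigid rotation of the space (tested). This
centroid-MST scheme replaces principal-curve iteration; its contract is
rank agreement with an underlying continuous process, not curve geometry.

The pseudotime heatmap matrix sorts cells by pseudotime, smooths each gene
with a centered rolling mean (width 50, truncated at the edges) and
z-scales rows for display; constant genes become zero rows.

Composition: percent of each sample's cells per cluster (columns sum to
100), per-cluster z-scaling across samples (sample SD), and ordering of
both axes by hierarchical clustering with distance 1 − Pearson r and Ward
linkage. Zero-variance rows are set to 0 and excluded from the correlation
clustering with a warning. 2^(−ΔCt) is provided for qPCR panels.

## Synthetic data

`synth.generate_counts` draws negative-binomial counts (gamma–Poisson,
variance μ + αμ², default α = 0.3) around log-normal baseline means with
log-normal library sizes (σ = 0.3, mean 20,000 — a typical deeply
sequenced well). Planted structure: per-cluster marker genes shifted by a
natural-log fold-change (default 2.0, 10 markers per cluster); per-module
latent factors entering member genes as loading × factor on the log-mean
scale; an optional smooth trajectory (uniform latent time driving sloped
genes, clusters as sequential time bins); mitochondrial genes overwritten
so a chosen fraction of cells sits at mito fraction ≈ 0.6 and the rest at
≈ 0.05, making the over-0.4 QC count exact by construction.
`generate_fpkm` produces continuous plate-style values with planted
modules, a known set of genes guaranteed to pass (or fail) the ≥5-in-5
filter, and an optional group-shifted module. `generate_tag_counts` draws
singlet profiles (dominant tag at signal_ratio × a Poisson ambient mean of
10), doublets as exact sums of two distinct-tag singlet draws, and
all-zero barcodes.

What this does **not** emulate: ambient RNA in the gene matrix, batch
effects, spliced/unspliced layers, instrument-specific tag noise (the
Poisson ambient model is a stand-in, not a claim about any chemistry), or
the gene-gene correlation structure of real transcriptomes. Passing tests
therefore demonstrate that the machinery recovers the structure it is
pointed at under controlled noise — not that any real dataset's module
count, cluster count or marker lists would be reproduced.

## Problem sizes

The drivers and tests run deliberately small problems: 150–600 cells,
80–300 genes, 20-seed repetitions for the stochastic guarantees, and 10⁶
simulated cells for the microwell cross-check — sizes at which every
guarantee is sharp while the full suite stays fast on a laptop. All
statistical acceptance checks (recovery rates, calibration counts) are
computed over fixed seed ranges and are exactly reproducible.

## Known limitations

* The static module cut (height 0.99) is coarser than dynamic tree
  cutting; module counts on real data are not comparable.
* The permutation PC test is a faithful-in-spirit reconstruction; its
  p-values are not numerically interchangeable with any specific tool's.
* Pseudotime is cluster-resolution: cells between centroids interpolate
  linearly, and heavily over-split clusterings can zig-zag the path.
* The demultiplexer assumes uniform tag representation; skewed pools
  shift both the (k−1)/k factor and the ambient model.
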