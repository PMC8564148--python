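# cardiosc

A tested re-implementation of a cardiac single-cell RNA-seq analysis
pipeline: microwell hashtag demultiplexing with a Poisson doublet model,
droplet- and plate-based quality control, graph clustering with
permutation-tested principal components and Wilcoxon marker detection,
signed co-expression modules ranked by random-forest importance, pseudotime
ordering from a defined start, and cluster-composition statistics. Every
stage is exercised on synthetic data with planted ground truth, so the whole
workflow is testable without access to any sequencing archive.

It is aimed at computational biologists who want the individual steps of
this style of analysis as plain, inspectable functions with explicit
contracts — not wrapped inside a monolithic framework object.

## The models in brief

**Microwell doublet rate.** Loading N cells on W microwells is Poisson with
λ = N/W cells per well. Among occupied wells, the multi-cell fraction is
[1 − (1+λ)e^(−λ)] / (1 − e^(−λ)). With k sample tags assigned uniformly, a
co-captured pair is *detectable* (carries two distinct tags) with
probability (k−1)/k, so

    D = [1 − (1+λ)e^(−λ)] / (1 − e^(−λ)) · (k−1)/k.

For the reference capture (N = 20,000, W = 200,000, k = 3) this gives
D = 3.28%. Barcodes are then ranked by log₂((c₁+1)/(c₂+1)) of their two
largest tag counts (after equalizing per-tag totals) and the lowest-scoring
D fraction is called doublets; all-zero barcodes are "not-detected". A
brute-force well simulator and an exact all-occupancy closed form
(`detectable_doublet_fraction_exact`) back the two-cell formula.

**Clustering.** ln(x/total·10⁶ + 1) normalization, binned-dispersion
variable genes, depth regression + z-scoring, PCA, a jackstraw-style
permutation test for PC significance (p ≤ 0.05), Louvain communities of the
shared-nearest-neighbor graph (resolution 1.5), and one-vs-rest Wilcoxon
markers gated by min.pct ≥ 0.1, ln-fold-change ≥ 0.25, Bonferroni-adjusted
p ≤ 0.05, positive only.

**Co-expression modules.** Signed adjacency ((1+r)/2)^12, topological
overlap, average-linkage clustering with a static cut, module eigengene =
first PC of the standardized member genes, and permutation-based
mean-decrease-in-OOB-accuracy random-forest ranking of modules against
experimental groups.

**Trajectory and composition.** Minimum-spanning-tree pseudotime over
cluster centroids in significant-PC space rooted at a chosen start cluster;
cluster×sample composition percentages, z-scaled per cluster and ordered by
Ward clustering of 1 − Pearson r; 2^(−ΔCt) for qPCR quantification.

## Worked example

```python
from cardiosc import demux, synth

model = demux.MicrowellModel(n_cells=20_000, n_wells=200_000, n_tags=3)
print(f"{demux.detectable_doublet_fraction(model)*100:.2f}%")   # 3.28%

tags, truth = synth.generate_tag_counts(
    n_singlets=570, n_doublets=30, n_zero=10,
    n_tags=3, signal_ratio=20, seed=42,
)
result = demux.demultiplex(tags, doublet_fraction=0.05)
print(result.counts().to_dict())
```

prints

```
3.28%
{'tag0': 198, 'tag1': 198, 'tag2': 174, 'DOUBLET': 30, 'NOT_DETECTED': 10}
```

— 3.28% is the model-derived doublet quantile for the reference capture;
on the simulated hashing run the ranking flags 30 barcodes (5% of the 600
scored), which here are exactly the 30 planted cross-tag doublets, labels
the 10 zero-count barcodes not-detected, and assigns the rest to their
dominant tag (100% of singlets correct; see
`analysis/02_demultiplex.py`).

The full synthetic study lives in `analysis/` as numbered drivers:

1. `01_simulate_inputs.py` — generate counts, FPKM and tag matrices with
   planted truth;
2. `02_demultiplex.py` — Poisson model + tag assignment, scored vs truth;
3. `03_qc_cluster_markers.py` — QC, normalization, PCA/permutation test,
   Louvain clustering, markers;
4. `04_coexpression_modules.py` — FPKM gene filter, signed network,
   modules, eigengenes, RF ranking;
5. `05_trajectory_composition.py` — pseudotime and composition tables.

Each writes its tables under `results/`.

## Layout

```
src/cardiosc/      library: synth, demux, qc, cluster, coexpr,
                   trajectory, composition, io, types
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    models, parameter choices, limitations
```
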