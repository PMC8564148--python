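#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/simulated/:
  * a droplet-style count matrix (MTX + features/barcodes TSV) with three
    planted cell clusters on a smooth trajectory, two latent-factor gene
    modules, and 10% of cells pushed over the 0.4 mitochondrial-fraction
    QC cutoff;
  * a plate-style FPKM matrix with two planted modules, one of them shifted
    between two experimental groups;
  * a sample-tag x barcode count matrix with singlets, 5% cross-tag
    doublets and a handful of zero-tag barcodes;
  * the ground-truth tables every later stage is scored against.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cardiosc import io, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 42

COUNT_DESIGN = synth.SynthDesign(
    n_genes=300, n_cells=600, n_clusters=3, marker_logfc=2.0,
    n_modules=2, module_size=40, factor_loading=1.0,
    mito_gene_count=10, mito_high_cell_fraction=0.1,
    trajectory=True, seed=SEED,
)
FPKM_DESIGN = synth.SynthDesign(
    n_genes=200, n_cells=150, n_modules=2, module_size=50,
    factor_loading=1.0, seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    counts, truth = synth.generate_counts(COUNT_DESIGN)
    io.write_mtx_dir(counts, OUT / "counts")
    cell_truth = pd.DataFrame(
        {
            "cluster": truth.cluster_of_cell,
            "pseudotime": truth.pseudotime_truth,
            "mito_high": truth.cluster_of_cell.index.isin(truth.mito_high_cells),
        }
    )
    cell_truth.to_csv(OUT / "counts_cell_truth.tsv", sep="\t")
    truth.module_of_gene.rename("module").to_csv(OUT / "counts_gene_truth.tsv", sep="\t")

    fpkm, ftruth = synth.generate_fpkm(
        FPKM_DESIGN, n_groups=2, group_shift_module=1, group_shift=3.0
    )
    io.write_dense_tsv(fpkm, OUT / "fpkm.tsv")
    pd.DataFrame(
        {"group": ftruth.group_of_cell.map({0: "sham", 1: "tac"})}
    ).to_csv(OUT / "fpkm_groups.tsv", sep="\t")
    ftruth.module_of_gene.rename("module").to_csv(OUT / "fpkm_gene_truth.tsv", sep="\t")

    tags, tag_truth = synth.generate_tag_counts(
        n_singlets=570, n_doublets=30, n_zero=10,
        n_tags=3, signal_ratio=20, seed=SEED,
    )
    io.write_tag_counts(tags, OUT / "tag_counts.tsv")
    truth_rows = pd.Series("singlet", index=tags.barcode_ids, name="identity")
    truth_rows[list(tag_truth.doublet_barcodes)] = "doublet"
    truth_rows[list(tag_truth.zero_barcodes)] = "zero"
    frame = truth_rows.to_frame()
    frame["true_tag"] = tag_truth.tag_of_barcode.reindex(tags.barcode_ids)
    frame.to_csv(OUT / "tag_truth.tsv", sep="\t")

    print(f"counts: {counts.n_genes} genes x {counts.n_cells} cells -> {OUT/'counts'}")
    print(f"fpkm:   {fpkm.n_genes} genes x {fpkm.n_cells} cells -> {OUT/'fpkm.tsv'}")
    print(f"tags:   {tags.counts.shape[0]} tags x {tags.counts.shape[1]} barcodes "
          f"(30 doublets, 10 zero) -> {OUT/'tag_counts.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
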