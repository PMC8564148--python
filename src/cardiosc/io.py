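"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket MTX plus ``features.tsv`` /
``barcodes.tsv`` sidecars (the CellRanger-style triplet); dense matrices,
tag counts and annotation tables as plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import ExpressionMatrix, TagCounts, Unit


def write_mtx_dir(mat: ExpressionMatrix, out_dir: str | Path) -> Path:
    """Write a counts matrix as ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparse = sp.csc_matrix(mat.values.to_numpy())
    scipy.io.mmwrite(out / "matrix.mtx", sparse)
    pd.Series(mat.gene_ids).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(mat.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    return out


def read_mtx_dir(in_dir: str | Path, unit: Unit = Unit.RAW_COUNTS) -> ExpressionMatrix:
    in_dir = Path(in_dir)
    sparse = scipy.io.mmread(in_dir / "matrix.mtx")
    genes = pd.read_csv(in_dir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None)[0]
    dense = np.asarray(sparse.todense())
    if unit is Unit.RAW_COUNTS:
        dense = dense.astype(np.int64)
    values = pd.DataFrame(dense, index=genes.to_numpy(), columns=cells.to_numpy())
    return ExpressionMatrix(values, unit)


def write_dense_tsv(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t")


def read_dense_tsv(path: str | Path, unit: Unit) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, unit)


def write_tag_counts(tags: TagCounts, path: str | Path) -> None:
    tags.counts.to_csv(path, sep="\t")


def read_tag_counts(path: str | Path) -> TagCounts:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return TagCounts(counts)
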