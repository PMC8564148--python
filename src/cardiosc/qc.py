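"""Cell and gene quality control, normalization and scaling.

Implements the filtering and normalization rules used for both capture
chemistries in this pipeline:

* droplet/microwell counts: drop cells with fewer than 500 detected genes
  or a mitochondrial read fraction strictly over 0.4, then drop genes seen
  in fewer than 5 remaining cells; library-size normalize to 1e6 and take
  ln(x + 1);
* plate-based FPKM: drop cardiomyocytes with fewer than 3,000 detected
  genes; keep, for the co-expression branch, genes at FPKM >= 5 in at
  least 5 cells (both bounds inclusive).

Boundary strictness follows the quoted thresholds exactly: a cell at mito
fraction 0.4 is retained ("over 0.4" filters), a cell at exactly 3,000
detected genes is retained ("less than 3,000" filters), a gene at FPKM 5.0
in 5 cells passes (">= 5 in at least 5").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, Unit

MITO_PREFIX = "mt-"


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 5
    max_mito_fraction: float = 0.4
    fpkm_floor: float = 5.0
    fpkm_min_cells: int = 5
    scale_factor: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if min(self.min_genes_per_cell, self.min_cells_per_gene, self.fpkm_min_cells) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class QCReport:
    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed_by_rule: dict = field(default_factory=dict)
    per_cell: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "removed_by_rule": self.removed_by_rule,
        }


def mito_gene_mask(gene_ids: pd.Index, mito_genes=None) -> np.ndarray:
    """Mitochondrial genes: caller-supplied list wins, else the mt- prefix."""
    if mito_genes is not None:
        return gene_ids.isin(set(mito_genes))
    return np.asarray(gene_ids.str.lower().str.startswith(MITO_PREFIX))


def filter_cells_genes(
    mat: ExpressionMatrix,
    th: QCThresholds | None = None,
    mito_genes=None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Droplet-style QC: cell filters first, then the gene-presence filter.

    Cells are dropped when detected genes < ``min_genes_per_cell`` or the
    mitochondrial fraction is strictly greater than ``max_mito_fraction``;
    genes are then dropped when detected in fewer than
    ``min_cells_per_gene`` of the surviving cells.
    """
    if mat.unit is not Unit.RAW_COUNTS:
        raise ValueError("filter_cells_genes expects raw counts")
    th = th or QCThresholds()
    counts = mat.values
    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    mito = mito_gene_mask(mat.gene_ids, mito_genes)
    with np.errstate(invalid="ignore"):
        mito_frac = counts.loc[mito].sum(axis=0) / totals.replace(0, np.nan)
    mito_frac = mito_frac.fillna(0.0)

    fail_genes = detected < th.min_genes_per_cell
    fail_mito = mito_frac > th.max_mito_fraction  # strict: exactly 0.4 is kept
    keep_cells = ~(fail_genes | fail_mito)

    kept = counts.loc[:, keep_cells]
    gene_presence = (kept > 0).sum(axis=1)
    keep_genes = gene_presence >= th.min_cells_per_gene
    out = counts.loc[keep_genes, keep_cells]
    if out.size == 0:
        warnings.warn("QC filtering removed everything", stacklevel=2)

    report = QCReport(
        cells_in=mat.n_cells,
        cells_out=int(keep_cells.sum()),
        genes_in=mat.n_genes,
        genes_out=int(keep_genes.sum()),
        removed_by_rule={
            "cell_min_genes": int(fail_genes.sum()),
            "cell_mito_fraction": int(fail_mito.sum()),
            "gene_min_cells": int((~keep_genes).sum()),
        },
        per_cell=pd.DataFrame(
            {"detected_genes": detected, "mito_fraction": mito_frac, "kept": keep_cells}
        ),
    )
    return ExpressionMatrix(out, Unit.RAW_COUNTS), report


def filter_cardiomyocytes(
    mat: ExpressionMatrix, min_detected: int = 3000
) -> ExpressionMatrix:
    """Drop plate-based cells with fewer than ``min_detected`` expressed genes.

    Detected means strictly positive FPKM; a cell at exactly the threshold
    is retained.
    """
    if mat.unit is not Unit.FPKM:
        raise ValueError("filter_cardiomyocytes expects an FPKM matrix")
    detected = (mat.values > 0).sum(axis=0)
    keep = detected >= min_detected
    if not keep.any():
        warnings.warn("no cardiomyocytes pass the detected-gene filter", stacklevel=2)
    return ExpressionMatrix(mat.values.loc[:, keep], Unit.FPKM)


def fpkm_module_gene_filter(
    mat: ExpressionMatrix, floor: float = 5.0, min_cells: int = 5
) -> list[str]:
    """Genes at FPKM >= ``floor`` in at least ``min_cells`` cells (inclusive)."""
    if mat.unit is not Unit.FPKM:
        raise ValueError("fpkm_module_gene_filter expects an FPKM matrix")
    n_pass = (mat.values >= floor).sum(axis=1)
    return list(mat.gene_ids[n_pass >= min_cells])


def normalize_log(
    mat: ExpressionMatrix, scale_factor: float = 1_000_000.0
) -> ExpressionMatrix:
    """Library-size normalize each cell to ``scale_factor`` and take ln(x + 1)."""
    if mat.unit is not Unit.RAW_COUNTS:
        raise ValueError("normalize_log expects raw counts")
    totals = mat.values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total cell: filter cells before normalizing")
    out = np.log1p(mat.values / totals * scale_factor)
    return ExpressionMatrix(out, Unit.LOG_NORM)


def select_variable_genes(
    mat: ExpressionMatrix,
    x_low: float = 0.1,
    x_high: float = np.inf,
    y_cutoff: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Highly-variable genes by binned, z-scored log variance/mean ratio.

    Per gene, on the de-logged values x = exp(v) - 1: mean is
    ln(mean(x) + 1) and dispersion is ln(var(x)/mean(x)).  Genes are cut
    into ``n_bins`` equal-frequency bins by mean; dispersion is z-scored
    within each bin; genes with x_low < mean < x_high and z > y_cutoff are
    returned.  A constant gene has dispersion -inf and is never selected.
    """
    if mat.unit is not Unit.LOG_NORM:
        raise ValueError("select_variable_genes expects log-normalized values")
    x = np.expm1(mat.values.to_numpy())
    gmean = x.mean(axis=1)
    gvar = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_stat = np.log1p(gmean)
        disp = np.where(gmean > 0, np.log(gvar / np.maximum(gmean, 1e-300)), -np.inf)
    disp = np.where(gvar > 0, disp, -np.inf)

    finite = np.isfinite(disp)
    z = np.full(mat.n_genes, -np.inf)
    if finite.any():
        ranks = pd.Series(mean_stat[finite]).rank(method="first")
        bins = np.ceil(ranks / (len(ranks) / n_bins)).clip(1, n_bins).astype(int)
        d = pd.Series(disp[finite])
        grouped = d.groupby(bins.to_numpy())
        mu = grouped.transform("mean")
        sd = grouped.transform("std")
        zb = (d - mu) / sd
        zb = zb.where(sd > 0, 0.0).fillna(0.0)  # singleton bin -> z = 0
        z[finite] = zb.to_numpy()

    keep = (mean_stat > x_low) & (mean_stat < x_high) & (z > y_cutoff)
    return list(mat.gene_ids[keep])


def scale_and_regress(
    mat: ExpressionMatrix, covariate: pd.Series | np.ndarray | None = None
) -> ExpressionMatrix:
    """Regress out a per-cell covariate and z-score each gene.

    Per gene: OLS of expression on the covariate (with intercept), residuals
    standardized to mean 0, sample SD 1.  The default covariate is the
    per-cell sum of de-logged values (a read-depth proxy).  A gene whose
    residual has zero variance becomes an all-zero row.
    """
    if mat.unit is not Unit.LOG_NORM:
        raise ValueError("scale_and_regress expects log-normalized values")
    y = mat.values.to_numpy()
    if covariate is None:
        covariate = np.expm1(y).sum(axis=0)
    c = np.asarray(covariate, dtype=float)
    if c.shape[0] != mat.n_cells:
        raise ValueError("covariate must have one value per cell")
    X = np.column_stack([np.ones_like(c), c])
    # One shared design matrix: residuals for all genes in a single solve.
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y - (X @ beta).T
    sd = resid.std(axis=1, ddof=1, keepdims=True)
    mean = resid.mean(axis=1, keepdims=True)
    # A residual SD that is float noise relative to the gene's own scale
    # (perfect fit) counts as zero variance.
    y_sd = y.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd <= 1e-10 * (y_sd + 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(~degenerate & (sd > 0), (resid - mean) / sd, 0.0)
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=mat.gene_ids, columns=mat.cell_ids), Unit.SCALED
    )
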