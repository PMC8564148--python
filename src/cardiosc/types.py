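"""Shared containers for the pipeline.

The central object is :class:`ExpressionMatrix`, a gene x cell matrix with an
explicit unit flag.  Keeping the unit on the container lets each stage check
it received the representation it expects (raw counts for QC filters, FPKM
for the co-expression branch, log-normalized for marker tests, scaled
residuals for PCA) instead of silently mixing scales.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Unit(str, enum.Enum):
    """Representation of expression values."""

    RAW_COUNTS = "raw_counts"
    FPKM = "fpkm"
    LOG_NORM = "log_norm"
    SCALED = "scaled"


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values with an explicit unit.

    Parameters
    ----------
    values
        DataFrame with genes as the index and cells as columns.
    unit
        One of :class:`Unit`.  ``RAW_COUNTS`` must be integer-valued and
        nonnegative; ``FPKM`` nonnegative reals.
    """

    values: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        arr = self.values.to_numpy()
        if self.unit in (Unit.RAW_COUNTS, Unit.FPKM):
            if arr.size and arr.min() < 0:
                raise ValueError(f"{self.unit.value} matrix has negative entries")
        if self.unit is Unit.RAW_COUNTS and arr.size:
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integer-valued")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        """Subset by gene and/or cell ids, preserving input order."""
        vals = self.values
        if genes is not None:
            keep = vals.index[vals.index.isin(set(genes))]
            vals = vals.loc[keep]
        if cells is not None:
            keep = vals.columns[vals.columns.isin(set(cells))]
            vals = vals[keep]
        return ExpressionMatrix(vals, self.unit)


@dataclass
class TagCounts:
    """Sample-tag x barcode read counts from a cell-hashing experiment."""

    counts: pd.DataFrame  # rows = tags, columns = barcodes
    normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate tag ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate barcode ids")
        arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("tag counts must be nonnegative")
        if not self.normalized and arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("raw tag counts must be integer-valued")

    @property
    def tag_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def barcode_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class CellAnnotation:
    """Per-cell labels accumulated along the pipeline."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def set(self, name: str, labels: pd.Series) -> None:
        self.table[name] = labels
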