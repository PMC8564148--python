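"""Hashtag demultiplexing for microwell-captured single cells.

Two pieces:

1. A Poisson microwell occupancy model giving the theoretically detectable
   doublet fraction.  With N cells loaded on W wells (lambda = N/W) and k
   sample tags used uniformly, the fraction of occupied wells holding two
   or more cells is [1 - (1 + lambda) e^-lambda] / (1 - e^-lambda); a
   multi-cell well is *detectable* only when its occupants carry at least
   two distinct tags, which happens with probability (k - 1)/k in the
   two-cell-dominated regime.

2. The tag-assignment procedure: normalize each tag's total to the minimum
   tag total, score every barcode by the log2 fold-change between its first
   and second most-counted tags, rank ascending, flag the lowest-scoring
   fraction (from the model above) as doublets, label all-zero barcodes
   "not-detected", and assign the rest to their top tag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TagCounts

DOUBLET = "DOUBLET"
NOT_DETECTED = "NOT_DETECTED"


@dataclass(frozen=True)
class MicrowellModel:
    """Poisson loading model: N cells, W microwells, k sample tags."""

    n_cells: int
    n_wells: int
    n_tags: int

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_wells, self.n_tags) < 1:
            raise ValueError("n_cells, n_wells and n_tags must all be >= 1")

    @property
    def lam(self) -> float:
        """Mean cells per well, N / W."""
        return self.n_cells / self.n_wells


def detectable_doublet_fraction(model: MicrowellModel) -> float:
    """Fraction of occupied wells expected to be detectable doublets.

    D = [1 - (1 + lambda) e^-lambda] / (1 - e^-lambda) * (k - 1) / k.
    Returns 0 for k = 1 (same-tag doublets cannot be detected).

    The (k - 1)/k factor is the probability that a *pair* of co-captured
    cells carries two distinct tags, so this expression is exact in the
    two-cell-well regime (lambda well below 1, the limited-dilution setting
    it is used in; at lambda = 0.1 it is within 1.1% of the full model).
    :func:`detectable_doublet_fraction_exact` keeps all occupancies.
    """
    lam = model.lam
    if lam <= 0:
        raise ValueError("lambda must be positive (no cells loaded?)")
    # -expm1(-lam) = 1 - e^-lam, stable for small lambda.
    occ = -math.expm1(-lam)
    multi = occ - lam * math.exp(-lam)
    k = model.n_tags
    return (multi / occ) * (k - 1) / k


def detectable_doublet_fraction_exact(model: MicrowellModel) -> float:
    """Detectable fraction keeping every well occupancy, not just pairs.

    An m-cell well is undetectable only when all m cells drew the same tag
    (probability k^(1-m)), so

        D = [1 - (1+lambda) e^-lambda
             - k e^-lambda (e^(lambda/k) - 1 - lambda/k)] / (1 - e^-lambda).

    This is the quantity the brute-force microwell simulation estimates; the
    two-cell form above underestimates it once triple-occupied wells become
    common.
    """
    lam = model.lam
    if lam <= 0:
        raise ValueError("lambda must be positive (no cells loaded?)")
    k = model.n_tags
    occ = -math.expm1(-lam)
    multi = occ - lam * math.exp(-lam)
    same_tag = k * math.exp(-lam) * (math.expm1(lam / k) - lam / k)
    return (multi - same_tag) / occ


@dataclass
class DemuxResult:
    """Per-barcode demultiplexing outcome.

    ``table`` columns: label (tag id, DOUBLET or NOT_DETECTED), top_tag,
    log2_fc, rank (ascending fold-change rank among scored barcodes; NaN for
    not-detected barcodes).
    """

    table: pd.DataFrame
    doublet_fraction: float

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts()


def normalize_tag_counts(tags: TagCounts) -> TagCounts:
    """Scale each tag row so all row totals equal the minimum positive total."""
    totals = tags.counts.sum(axis=1)
    positive = totals[totals > 0]
    if positive.empty:
        raise ValueError("all tag rows are zero")
    if (totals == 0).any():
        warnings.warn("tag rows with zero total left as zero", stacklevel=2)
    factors = (positive.min() / totals).where(totals > 0, 0.0)
    scaled = tags.counts.mul(factors, axis=0)
    return TagCounts(scaled, normalized=True)


def score_barcodes(tags: TagCounts) -> pd.DataFrame:
    """Score each barcode by log2((top1 + 1) / (top2 + 1)) of normalized counts.

    Returns a DataFrame indexed by barcode with columns top_tag, second_tag,
    log2_fc, total; all-zero barcodes get NaN scores (labelled not-detected
    downstream).  The pseudocount keeps the score finite when the second
    count is zero.
    """
    if not tags.normalized:
        raise ValueError("score_barcodes expects normalized tag counts")
    arr = tags.counts.to_numpy(dtype=float)
    order = np.argsort(-arr, axis=0, kind="stable")
    top_idx, second_idx = order[0], order[1] if arr.shape[0] > 1 else order[0]
    cols = np.arange(arr.shape[1])
    c1 = arr[top_idx, cols]
    c2 = arr[second_idx, cols] if arr.shape[0] > 1 else np.zeros_like(c1)
    log2_fc = np.log2((c1 + 1.0) / (c2 + 1.0))
    total = arr.sum(axis=0)
    zero = total == 0
    tag_ids = tags.tag_ids.to_numpy()
    out = pd.DataFrame(
        {
            "top_tag": np.where(zero, None, tag_ids[top_idx]),
            "second_tag": np.where(zero, None, tag_ids[second_idx]),
            "log2_fc": np.where(zero, np.nan, log2_fc),
            "total": total,
        },
        index=tags.barcode_ids,
    )
    return out


def call_doublets(scores: pd.DataFrame, doublet_fraction: float) -> DemuxResult:
    """Label barcodes as a tag, DOUBLET or NOT_DETECTED.

    Scored barcodes are sorted ascending by (log2_fc, total, barcode id) and
    the first ceil(doublet_fraction * n_scored) are flagged as doublets; the
    rest keep their top tag.  Barcodes with no score are NOT_DETECTED.
    """
    if not 0.0 <= doublet_fraction < 1.0:
        raise ValueError("doublet_fraction must be in [0, 1)")
    scored = scores[scores["log2_fc"].notna()].copy()
    # Deterministic tie-break: score, then total, then barcode id.
    scored["_bc"] = scored.index
    scored = scored.sort_values(["log2_fc", "total", "_bc"], kind="stable")
    n_doublets = math.ceil(doublet_fraction * len(scored))
    labels = scored["top_tag"].astype(object).copy()
    labels.iloc[:n_doublets] = DOUBLET
    rank = pd.Series(np.arange(1, len(scored) + 1), index=scored.index, dtype=float)

    table = pd.DataFrame(index=scores.index)
    table["label"] = labels.reindex(scores.index).fillna(NOT_DETECTED)
    table["top_tag"] = scores["top_tag"]
    table["log2_fc"] = scores["log2_fc"]
    table["rank"] = rank.reindex(scores.index)
    return DemuxResult(table=table, doublet_fraction=doublet_fraction)


def demultiplex(
    tags: TagCounts,
    model: MicrowellModel | None = None,
    doublet_fraction: float | None = None,
) -> DemuxResult:
    """Full pipeline: normalize -> score -> rank -> call.

    ``doublet_fraction`` overrides the model-derived value when given.
    """
    if doublet_fraction is None:
        if model is None:
            raise ValueError("need a MicrowellModel or an explicit doublet_fraction")
        doublet_fraction = detectable_doublet_fraction(model)
    normalized = normalize_tag_counts(tags)
    scores = score_barcodes(normalized)
    return call_doublets(scores, doublet_fraction)
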