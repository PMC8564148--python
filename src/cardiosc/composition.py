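"""Cluster-composition statistics and small quantification utilities.

For each sample, the percentage of its cells falling in every cluster is
computed (columns sum to 100); each cluster row is then z-scaled across
samples and both axes are ordered by hierarchical clustering with
1 - Pearson correlation distance and Ward linkage — the standard recipe for
a composition heatmap.  Also provides the 2^-dCt relative-quantification
transform used for qPCR validation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .cluster import ClusterAssignment


@dataclass
class CompositionTable:
    raw_percent: pd.DataFrame  # clusters x samples, columns sum to 100
    z_scaled: pd.DataFrame
    cluster_order: list
    sample_order: list


def _correlation_order(frame: pd.DataFrame, axis: int) -> list:
    """Leaf order from Ward clustering of 1 - Pearson r along one axis."""
    mat = frame.to_numpy() if axis == 0 else frame.to_numpy().T
    labels = list(frame.index if axis == 0 else frame.columns)
    if mat.shape[0] < 3:
        return labels
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(mat)
    cor = np.nan_to_num(cor, nan=0.0)
    dist = 1.0 - cor
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return [labels[i] for i in hierarchy.leaves_list(Z)]


def composition_table(
    clusters: ClusterAssignment, sample_of_cell: pd.Series
) -> CompositionTable:
    """Cluster x sample composition percentages, z-scaled and ordered."""
    labels = clusters.cluster_of_cell
    samples = sample_of_cell.reindex(labels.index)
    if samples.isna().any():
        raise ValueError("every cell needs a sample label")
    counts = pd.crosstab(labels, samples)
    raw = counts.div(counts.sum(axis=0), axis=1) * 100.0

    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance cluster rows excluded from "
            "correlation clustering",
            stacklevel=2,
        )
    z = raw.sub(mean, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)

    informative = z.loc[~degenerate] if (~degenerate).any() else z
    cluster_order = _correlation_order(informative, axis=0)
    cluster_order += [c for c in z.index if c not in cluster_order]
    sample_order = _correlation_order(informative, axis=1)
    return CompositionTable(
        raw_percent=raw,
        z_scaled=z,
        cluster_order=cluster_order,
        sample_order=sample_order,
    )


def relative_quantification(ct_target: float, ct_reference: float) -> float:
    """qPCR relative quantification, 2^-(Ct_target - Ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))
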