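"""Pseudotime ordering from a defined starting cluster.

Cells are ordered along a minimum spanning tree of cluster centroids in
significant-PC space: the tree is rooted at a caller-chosen start cluster
(the biology defines it — e.g. where reference-condition cells are
enriched), each cell is projected onto its nearest tree segment, and
pseudotime is the arc length from the root to the projection.  This is a
deliberately simple cluster-level trajectory: the contract is rank
agreement with an underlying continuous process, not curve geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .cluster import ClusterAssignment, ReducedSpace
from .types import ExpressionMatrix, Unit


@dataclass
class PseudotimeOrder:
    pseudotime: pd.Series  # per cell, min 0
    start_cluster: int
    lineage_paths: list  # ordered cluster labels, root -> each leaf

    def ordered_cells(self) -> pd.Index:
        return self.pseudotime.sort_values(kind="stable").index


def start_cluster_from_reference(
    clusters: ClusterAssignment, group_of_cell: pd.Series, reference_group
) -> int:
    """Cluster with the highest fraction of cells from the reference group."""
    groups = group_of_cell.reindex(clusters.cluster_of_cell.index)
    frac = (
        (groups == reference_group)
        .groupby(clusters.cluster_of_cell)
        .mean()
        .sort_values(ascending=False, kind="stable")
    )
    return int(frac.index[0])


def pseudotime(
    space: ReducedSpace,
    clusters: ClusterAssignment,
    start_cluster: int,
    significant_pcs=None,
) -> PseudotimeOrder:
    """Centroid-MST pseudotime rooted at ``start_cluster``.

    With a single cluster, pseudotime is arc length along the cells' first
    principal direction instead.
    """
    labels = clusters.cluster_of_cell
    uniq = np.unique(labels.to_numpy())
    if start_cluster not in uniq:
        raise ValueError(f"unknown start cluster {start_cluster}")
    cols = list(significant_pcs) if significant_pcs is not None else list(space.pc_names)
    coords = space.scores[cols].to_numpy()
    cells = space.scores.index

    if uniq.size == 1:
        centered = coords - coords.mean(axis=0, keepdims=True)
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        arc = centered @ Vt[0]
        pt = arc - arc.min()
        return PseudotimeOrder(
            pd.Series(pt, index=cells), int(start_cluster), [[int(start_cluster)]]
        )

    centroids = np.vstack(
        [coords[(labels == c).to_numpy()].mean(axis=0) for c in uniq]
    )
    dmat = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dmat).toarray()
    mst = np.maximum(mst, mst.T)  # undirected

    # Root the tree at the start cluster; arc length of every node from root.
    root = int(np.flatnonzero(uniq == start_cluster)[0])
    n_nodes = uniq.size
    parent = np.full(n_nodes, -1)
    arc = np.full(n_nodes, np.nan)
    arc[root] = 0.0
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in np.flatnonzero(mst[u] > 0):
            if np.isnan(arc[v]):
                parent[v] = u
                arc[v] = arc[u] + mst[u, v]
                stack.append(v)

    # Lineages: paths from root to each leaf.
    children = {u: [v for v in range(n_nodes) if parent[v] == u] for u in range(n_nodes)}
    paths = []

    def walk(u, path):
        path = path + [int(uniq[u])]
        if not children[u]:
            paths.append(path)
        for v in children[u]:
            walk(v, path)

    walk(root, [])

    # Project each cell onto its nearest directed (parent -> child) segment.
    edges = [(parent[v], v) for v in range(n_nodes) if parent[v] >= 0]
    best_d = np.full(coords.shape[0], np.inf)
    best_pt = np.zeros(coords.shape[0])
    for u, v in edges:
        a, b = centroids[u], centroids[v]
        ab = b - a
        seg_len = np.linalg.norm(ab)
        t = np.clip((coords - a) @ ab / (seg_len**2), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(coords - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_pt[better] = arc[u] + t[better] * seg_len
    best_pt -= best_pt.min()
    return PseudotimeOrder(pd.Series(best_pt, index=cells), int(start_cluster), paths)


def pseudotime_heatmap_matrix(
    expr: ExpressionMatrix,
    genes,
    order: PseudotimeOrder,
    window: int = 50,
) -> pd.DataFrame:
    """Pseudotime-ordered, rolling-mean-smoothed, row-z-scaled display matrix.

    Columns are cells sorted by pseudotime; each gene row is smoothed with a
    centered rolling mean of width ``window`` (truncated at the edges) and
    z-scaled for display.  ``window=1`` reproduces the raw reordered values
    (up to the z-scaling).
    """
    if expr.unit is not Unit.LOG_NORM:
        raise ValueError("pseudotime_heatmap_matrix expects log-normalized values")
    genes = list(genes)
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    if window < 1:
        raise ValueError("window must be >= 1")
    ordered = order.ordered_cells()
    if window > len(ordered):
        raise ValueError("window larger than the number of cells")
    sub = expr.values.loc[genes, ordered]
    smooth = sub.T.rolling(window, center=True, min_periods=1).mean().T
    mean = smooth.mean(axis=1)
    sd = smooth.std(axis=1, ddof=1)
    z = smooth.sub(mean, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    return z
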