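"""Dimensionality reduction, graph clustering and marker detection.

The workflow mirrors the classic single-cell recipe: PCA on scaled
expression restricted to highly-variable genes, a permutation ("jackstraw"
style) test to pick statistically enriched components, a shared-nearest-
neighbor graph clustered by modularity optimization at a chosen
resolution, and one-vs-rest Wilcoxon marker detection with min.pct,
log-fold-change and Bonferroni gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .types import ExpressionMatrix, Unit

SNN_PRUNE = 1.0 / 15.0  # Jaccard cutoff below which SNN edges are dropped


@dataclass
class ReducedSpace:
    """PCA scores/loadings plus per-PC significance once tested."""

    scores: pd.DataFrame  # cells x PCs
    loadings: pd.DataFrame  # genes x PCs
    variance_explained: pd.Series
    pc_pvalues: pd.Series | None = None

    @property
    def pc_names(self) -> pd.Index:
        return self.scores.columns


@dataclass
class ClusterAssignment:
    cluster_of_cell: pd.Series
    resolution: float
    k_neighbors: int

    @property
    def labels(self) -> np.ndarray:
        return self.cluster_of_cell.to_numpy()

    def cluster_sizes(self) -> pd.Series:
        return self.cluster_of_cell.value_counts().sort_index()


def pca(
    scaled: ExpressionMatrix,
    variable_genes=None,
    n_pcs: int = 100,
) -> ReducedSpace:
    """PCA of cells in scaled-expression space restricted to variable genes.

    Scaled rows are already centered, so the SVD of the cell x gene matrix
    is the PCA.  Signs are fixed so each component's largest-magnitude gene
    loading is positive, making results deterministic.
    """
    if scaled.unit is not Unit.SCALED:
        raise ValueError("pca expects scaled residuals")
    mat = scaled.values
    if variable_genes is not None:
        keep = mat.index[mat.index.isin(set(variable_genes))]
        mat = mat.loc[keep]
    X = mat.to_numpy().T  # cells x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if n_pcs > rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank {rank}; truncating", stacklevel=2)
        n_pcs = rank
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # Sign convention: largest-|loading| entry positive.
    flip = np.sign(Vt[np.arange(n_pcs), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    names = [f"PC{i+1}" for i in range(n_pcs)]
    n_cells = X.shape[0]
    return ReducedSpace(
        scores=pd.DataFrame(U * S, index=scaled.cell_ids, columns=names),
        loadings=pd.DataFrame(Vt.T, index=mat.index, columns=names),
        variance_explained=pd.Series(S**2 / max(n_cells - 1, 1), index=names),
    )


def permutation_pc_test(
    scaled: ExpressionMatrix,
    variable_genes=None,
    n_pcs: int = 100,
    n_replicates: int = 100,
    perm_gene_fraction: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], ReducedSpace]:
    """Permutation test of per-PC enrichment (jackstraw style).

    Per replicate a random ``perm_gene_fraction`` of genes have their cell
    order permuted; PCA is recomputed and the permuted genes' absolute
    loadings pooled into a per-PC null.  Each PC's p-value is a one-sided
    Mann-Whitney test of whether the observed |loading| distribution is
    stochastically larger than its null.  Returns the PCs at p <= alpha and
    the (annotated) reduced space.
    """
    space = pca(scaled, variable_genes, n_pcs=n_pcs)
    genes = space.loadings.index
    n_genes = len(genes)
    n_perm = int(round(perm_gene_fraction * n_genes))
    if n_perm < 1:
        raise ValueError("perm_gene_fraction too small: no genes to permute")
    rng = np.random.default_rng(seed)
    mat = scaled.values.loc[genes].to_numpy()
    n_keep = space.scores.shape[1]

    null: list[np.ndarray] = []
    for _ in range(n_replicates):
        pick = rng.choice(n_genes, size=n_perm, replace=False)
        perturbed = mat.copy()
        for g in pick:
            perturbed[g] = perturbed[g, rng.permutation(mat.shape[1])]
        X = perturbed.T
        X = X - X.mean(axis=0, keepdims=True)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        null.append(np.abs(Vt[:n_keep, pick]))
    null_arr = np.concatenate(null, axis=1)  # PCs x (reps * n_perm)

    observed = np.abs(space.loadings.to_numpy().T)  # PCs x genes
    pvals = np.empty(n_keep)
    for j in range(n_keep):
        pvals[j] = stats.mannwhitneyu(
            observed[j], null_arr[j], alternative="greater"
        ).pvalue
    space.pc_pvalues = pd.Series(pvals, index=space.pc_names)
    significant = [pc for pc, p in space.pc_pvalues.items() if p <= alpha]
    return significant, space


def snn_graph(
    coords: np.ndarray, k_neighbors: int = 20, prune: float = SNN_PRUNE
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighborhood is itself plus its (k-1) nearest neighbors in
    Euclidean space; edge weight between two cells is the Jaccard overlap of
    their neighborhoods, pruned below ``prune``.
    """
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    adj = nn.kneighbors_graph(coords, mode="connectivity")  # includes self
    shared = adj @ adj.T
    shared = shared.tocoo()
    union = 2 * k_neighbors - shared.data
    jac = shared.data / union
    keep = jac >= prune
    graph = sp.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    graph.setdiag(0)
    graph.eliminate_zeros()
    return graph


def graph_cluster(
    space: ReducedSpace,
    significant_pcs,
    resolution: float = 1.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Modularity (Louvain) communities of the SNN graph in significant-PC space."""
    pcs = list(significant_pcs)
    if not pcs:
        raise ValueError("need at least one significant PC")
    coords = space.scores[pcs].to_numpy()
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    if np.ptp(coords, axis=0).max() == 0:
        # Degenerate input: every cell identical, nothing to partition.
        return ClusterAssignment(
            cluster_of_cell=pd.Series(0, index=space.scores.index),
            resolution=resolution,
            k_neighbors=k_neighbors,
        )
    graph = snn_graph(coords, k_neighbors=k_neighbors)
    G = nx.from_scipy_sparse_array(graph)
    G.add_nodes_from(range(n))
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    # Deterministic labels: big clusters first, ties by smallest member index.
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(communities):
        labels[list(members)] = lab
    return ClusterAssignment(
        cluster_of_cell=pd.Series(labels, index=space.scores.index),
        resolution=resolution,
        k_neighbors=k_neighbors,
    )


def log_fold_change(in_vals: np.ndarray, out_vals: np.ndarray) -> np.ndarray:
    """Natural-log fold-change of de-logged means, ln((m_in+1)/(m_out+1))."""
    m_in = np.expm1(in_vals).mean(axis=1)
    m_out = np.expm1(out_vals).mean(axis=1)
    return np.log((m_in + 1.0) / (m_out + 1.0))


def find_markers(
    norm: ExpressionMatrix,
    clusters: ClusterAssignment,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table under the standard gates.

    A gene is tested for a cluster only when expressed in >= ``min_pct`` of
    in-cluster cells and its natural-log fold-change is >= ``logfc_threshold``
    (positive markers only).  Bonferroni corrects over the full hypothesis
    family examined — every (gene, cluster) pair — because the fold-change
    gate selects for extreme observed differences and correcting only over
    gated genes would be anti-conservative.  Rows with adjusted p <=
    ``alpha`` are returned sorted by p then descending fold-change.
    """
    if norm.unit is not Unit.LOG_NORM:
        raise ValueError("find_markers expects log-normalized values")
    labels = clusters.cluster_of_cell.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    uniq = np.unique(labels.to_numpy())
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    vals = norm.values.to_numpy()
    rows = []
    n_comparisons = 0
    for c in uniq:
        mask = (labels == c).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        n_comparisons += 1
        in_vals, out_vals = vals[:, mask], vals[:, ~mask]
        pct_in = (in_vals > 0).mean(axis=1)
        pct_out = (out_vals > 0).mean(axis=1)
        lfc = log_fold_change(in_vals, out_vals)
        gate = (pct_in >= min_pct) & (lfc >= logfc_threshold)
        idx = np.flatnonzero(gate)
        if idx.size == 0:
            continue
        res = stats.mannwhitneyu(
            in_vals[idx], out_vals[idx], axis=1, alternative="two-sided"
        )
        for i, g in enumerate(idx):
            rows.append(
                {
                    "cluster": c,
                    "gene": norm.gene_ids[g],
                    "log_fc": lfc[g],
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                    "p_raw": res.pvalue[i],
                }
            )
    table = pd.DataFrame(
        rows, columns=["cluster", "gene", "log_fc", "pct_in", "pct_out", "p_raw"]
    )
    if table.empty:
        table["p_bonferroni"] = pd.Series(dtype=float)
        return table
    n_family = norm.n_genes * n_comparisons
    table["p_bonferroni"] = np.minimum(table["p_raw"] * n_family, 1.0)
    table = table[table["p_bonferroni"] <= alpha]
    table = table.sort_values(
        ["p_raw", "log_fc"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return table
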