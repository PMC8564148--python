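"""Signed weighted co-expression modules, eigengenes and RF ranking.

The network is signed: adjacency a_ij = ((1 + cor(g_i, g_j)) / 2)^beta, so
anticorrelated genes get near-zero adjacency instead of being folded onto
correlated ones.  Modules come from average-linkage clustering of the
topological-overlap dissimilarity with a static tree cut; each module is
summarized per cell by its eigengene (first principal component of the
standardized member genes, unit variance, sign-aligned with the module's
mean profile).  Modules are then ranked by permutation-based random-forest
importance — the mean decrease in out-of-bag accuracy when one eigengene's
values are shuffled — for how well they separate experimental groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier

from .types import ExpressionMatrix

STATIC_CUT_HEIGHT = 0.99


@dataclass
class ModuleSet:
    """Gene-module assignment (label 0 = unassigned) plus eigengenes."""

    module_of_gene: pd.Series
    eigengenes: pd.DataFrame | None = None  # cells x modules
    soft_power: float = 12.0
    min_module_size: int = 30

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.module_of_gene[self.module_of_gene > 0]
        return assigned.value_counts().sort_index()

    def genes_of(self, module: int) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])


@dataclass
class ImportanceRanking:
    table: pd.DataFrame  # module, mean_decrease_accuracy, rank
    oob_accuracy_baseline: float
    n_trees: int
    seed: int

    @property
    def top_module(self) -> str:
        return self.table.iloc[0]["module"]


def build_signed_network(
    expr: ExpressionMatrix, soft_power: float = 12.0
) -> pd.DataFrame:
    """Signed adjacency ((1 + r)/2)^beta from gene-gene Pearson correlation."""
    vals = expr.values.to_numpy()
    if vals.shape[0] < 2 or vals.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    if (vals.std(axis=1) == 0).any():
        raise ValueError("zero-variance gene: filter before building the network")
    cor = np.corrcoef(vals)
    adj = ((1.0 + cor) / 2.0) ** soft_power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.gene_ids, columns=expr.gene_ids)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted network (diagonal 1)."""
    A = adjacency.to_numpy().copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    adjacency: pd.DataFrame, min_module_size: int = 30
) -> ModuleSet:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The gene dendrogram is cut at a fixed height; clusters smaller than
    ``min_module_size`` are left unassigned (label 0).  Surviving modules
    are relabelled 1..M by decreasing size.
    """
    genes = adjacency.index
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size: nothing assigned", stacklevel=2)
        return ModuleSet(
            pd.Series(0, index=genes), min_module_size=min_module_size
        )
    diss = 1.0 - topological_overlap(adjacency).to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0  # symmetrize away float noise
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=STATIC_CUT_HEIGHT, criterion="distance")
    labels = np.zeros(len(genes), dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_label = 1
    for cl in sizes[sizes >= min_module_size].index:
        labels[raw == cl] = next_label
        next_label += 1
    return ModuleSet(pd.Series(labels, index=genes), min_module_size=min_module_size)


def module_eigengene(expr: ExpressionMatrix, genes) -> pd.Series:
    """First principal component of a module's standardized genes, per cell.

    Genes are z-scored across cells; the PC1 cell score is scaled to unit
    variance and sign-oriented so it correlates positively with the module's
    mean standardized expression.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    sub = expr.values.loc[genes].to_numpy()
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene inside module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    U, S, Vt = np.linalg.svd(z, full_matrices=False)
    me = Vt[0]
    me = me / me.std(ddof=1)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    return pd.Series(me, index=expr.cell_ids)


def module_eigengenes(expr: ExpressionMatrix, modules: ModuleSet) -> pd.DataFrame:
    """Eigengene matrix (cells x modules) for all assigned modules."""
    cols = {}
    for m in modules.module_sizes.index:
        cols[f"M{m}"] = module_eigengene(expr, modules.genes_of(m))
    return pd.DataFrame(cols, index=expr.cell_ids)


def module_mean_expression(expr: ExpressionMatrix, modules: ModuleSet) -> pd.DataFrame:
    """Mean standardized expression per module — alternative summary to the ME."""
    cols = {}
    for m in modules.module_sizes.index:
        sub = expr.values.loc[modules.genes_of(m)].to_numpy()
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        cols[f"M{m}"] = pd.Series(z.mean(axis=0), index=expr.cell_ids)
    return pd.DataFrame(cols, index=expr.cell_ids)


def rank_modules_rf(
    eigengenes: pd.DataFrame,
    groups: pd.Series,
    n_trees: int = 1000,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank modules by permutation mean decrease in OOB accuracy.

    A bagged ensemble of decision trees (sqrt(m) candidate features per
    split) classifies each cell's group from the module eigengenes.  Per
    tree, the out-of-bag accuracy is compared with the accuracy after
    shuffling one eigengene's values on the OOB cells; a module's importance
    is the mean drop over trees.  Modules are returned ranked descending.
    """
    y = groups.reindex(eigengenes.index)
    if y.isna().any():
        raise ValueError("every cell needs a group label")
    classes, y_codes = np.unique(y.to_numpy(), return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(y_codes)
    if counts.min() < 5:
        raise ValueError("every group needs at least 5 cells")
    X = eigengenes.to_numpy()
    n, m = X.shape
    rng = np.random.default_rng(seed)

    drops = np.zeros((n_trees, m))
    oob_accs = np.empty(n_trees)
    used = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y_codes[boot])
        pred = tree.predict(X[oob])
        acc = (pred == y_codes[oob]).mean()
        oob_accs[t] = acc
        used[t] = True
        for j in range(m):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            acc_p = (tree.predict(Xp) == y_codes[oob]).mean()
            drops[t, j] = acc - acc_p
    if not used.any():
        raise RuntimeError("no tree had out-of-bag samples")
    importance = drops[used].mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    table = pd.DataFrame(
        {
            "module": eigengenes.columns[order],
            "mean_decrease_accuracy": importance[order],
            "rank": np.arange(1, m + 1),
        }
    )
    return ImportanceRanking(
        table=table,
        oob_accuracy_baseline=float(oob_accs[used].mean()),
        n_trees=n_trees,
        seed=seed,
    )
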