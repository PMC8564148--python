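import numpy as np
import pandas as pd
import pytest

from cardiosc import cluster, qc, synth
from cardiosc.types import ExpressionMatrix, Unit


@pytest.fixture(scope="session")
def small_counts():
    """Three well-separated planted clusters, no mito-high cells."""
    design = synth.SynthDesign(
        n_genes=150, n_cells=200, n_clusters=3, marker_logfc=2.0, seed=11
    )
    return synth.generate_counts(design)


@pytest.fixture(scope="session")
def small_pipeline(small_counts):
    """Counts run through QC -> log-norm -> variable genes -> scaling -> PCA."""
    mat, truth = small_counts
    filt, _ = qc.filter_cells_genes(mat, qc.QCThresholds(min_genes_per_cell=50))
    norm = qc.normalize_log(filt)
    hv = qc.select_variable_genes(norm)
    scaled = qc.scale_and_regress(norm)
    sig, space = cluster.permutation_pc_test(
        scaled, hv, n_pcs=20, n_replicates=30, perm_gene_fraction=0.05, seed=0
    )
    return {
        "truth": truth,
        "norm": norm,
        "scaled": scaled,
        "variable_genes": hv,
        "significant_pcs": sig,
        "space": space,
    }


def blob_space(centers, n_per, sd=1.0, seed=0, n_dims=5):
    """A ReducedSpace of Gaussian blobs around given centroids (test helper)."""
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        c = np.asarray(c, dtype=float)
        if c.size < n_dims:
            c = np.pad(c, (0, n_dims - c.size))
        pts.append(rng.normal(0.0, sd, size=(n_per, n_dims)) + c)
        labels += [i] * n_per
    coords = np.vstack(pts)
    cells = [f"cell{i:04d}" for i in range(coords.shape[0])]
    names = [f"PC{i+1}" for i in range(n_dims)]
    space = cluster.ReducedSpace(
        scores=pd.DataFrame(coords, index=cells, columns=names),
        loadings=pd.DataFrame(np.eye(n_dims), columns=names),
        variance_explained=pd.Series(np.ones(n_dims), index=names),
    )
    return space, pd.Series(labels, index=cells)


def as_log_norm(values: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(values, Unit.LOG_NORM)
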