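"""Synthetic single-cell data with planted ground truth.

Generates the three kinds of input the pipeline consumes:

* negative-binomial count matrices with planted cell clusters (marker genes
  at a chosen natural-log fold-change), planted latent-factor gene modules,
  an optional smooth trajectory, and mitochondrial genes whose per-cell
  fraction straddles the 0.4 QC cutoff;
* FPKM-style continuous matrices for the plate-based branch, with planted
  modules and a known set of genes passing the FPKM >= 5-in-5 filter;
* sample-tag x barcode count matrices containing singlets, cross-tag
  doublets and zero-tag barcodes.

A Monte-Carlo microwell simulator serves as the brute-force oracle for the
closed-form detectable-doublet fraction.

Every generator draws all randomness from a single ``numpy`` Generator
seeded by the design, so identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, TagCounts, Unit

# Mito-fraction targets used by generate_counts: "high" cells land well above
# the 0.4 QC cutoff, the rest well below, so the planted over-threshold cell
# count is exact despite count noise.
_MITO_HIGH_TARGET = 0.6
_MITO_LOW_TARGET = 0.05


@dataclass
class SynthDesign:
    """Parameters of a synthetic count/FPKM matrix.

    ``marker_logfc`` is the natural-log fold-change applied to each planted
    marker gene inside its cluster.  ``nb_dispersion`` is the quadratic
    overdispersion alpha of the negative binomial (variance mu + alpha mu^2).
    """

    n_genes: int = 200
    n_cells: int = 300
    n_clusters: int = 3
    marker_logfc: float = 2.0
    n_modules: int = 2
    module_size: int = 30
    factor_loading: float = 1.0
    nb_dispersion: float = 0.3
    mito_gene_count: int = 10
    mito_high_cell_fraction: float = 0.0
    trajectory: bool = False
    seed: int = 0
    markers_per_cluster: int = 10
    library_size_sigma: float = 0.3
    mean_library_size: float = 20_000.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_clusters", "mito_gene_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_modules < 0 or self.module_size < 0:
            raise ValueError("module counts must be nonnegative")
        if self.n_modules > 0 and self.module_size < 2:
            raise ValueError(
                "module_size < 2: a module eigengene needs at least 2 genes"
            )
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.mito_high_cell_fraction <= 1.0:
            raise ValueError("mito_high_cell_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class SynthTruth:
    """Planted ground truth recorded alongside a generated dataset."""

    cluster_of_cell: pd.Series | None = None
    module_of_gene: pd.Series | None = None
    factor_values: pd.DataFrame | None = None
    pseudotime_truth: pd.Series | None = None
    marker_genes: dict = field(default_factory=dict)
    group_of_cell: pd.Series | None = None
    expressed_genes: list | None = None
    mito_high_cells: list | None = None
    doublet_barcodes: set = field(default_factory=set)
    zero_barcodes: set = field(default_factory=set)
    tag_of_barcode: pd.Series | None = None


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _plan_genes(design: SynthDesign):
    """Lay out gene roles: mito genes first, then module genes, then markers."""
    genes = _ids("gene", design.n_genes)
    for i in range(design.mito_gene_count):
        genes[i] = f"mt-{i:03d}"
    module_of_gene = np.zeros(design.n_genes, dtype=int)
    pos = design.mito_gene_count
    for m in range(design.n_modules):
        module_of_gene[pos : pos + design.module_size] = m + 1
        pos += design.module_size
    marker_start = pos
    return genes, module_of_gene, marker_start


def generate_counts(design: SynthDesign) -> tuple[ExpressionMatrix, SynthTruth]:
    """Generate a negative-binomial count matrix with planted structure.

    Returns the raw-count :class:`ExpressionMatrix` (genes x cells) and the
    :class:`SynthTruth` recording cluster labels, module memberships, latent
    factor values, marker genes, the planted trajectory coordinate (if any)
    and which cells carry a high mitochondrial fraction.
    """
    rng = np.random.default_rng(design.seed)
    genes, module_of_gene, marker_start = _plan_genes(design)
    cells = _ids("cell", design.n_cells)

    # Baseline relative expression per gene (log-normal across genes).
    log_base = rng.normal(0.0, 1.0, size=design.n_genes)

    # Cluster labels and the optional trajectory coordinate.
    if design.trajectory:
        t = np.sort(rng.uniform(0.0, 1.0, size=design.n_cells))
        rng.shuffle(t)
        cluster = np.minimum(
            (t * design.n_clusters).astype(int), design.n_clusters - 1
        )
        pseudotime_truth = pd.Series(t, index=cells)
    else:
        cluster = np.arange(design.n_cells) % design.n_clusters
        rng.shuffle(cluster)
        pseudotime_truth = None

    log_mu = np.tile(log_base[:, None], (1, design.n_cells))

    # Planted cluster markers: marker_logfc added inside the home cluster.
    marker_genes: dict[int, list[str]] = {}
    pos = marker_start
    for c in range(design.n_clusters):
        idx = np.arange(pos, min(pos + design.markers_per_cluster, design.n_genes))
        pos += design.markers_per_cluster
        marker_genes[c] = [genes[i] for i in idx]
        if design.marker_logfc != 0.0 and idx.size:
            log_mu[np.ix_(idx, np.flatnonzero(cluster == c))] += design.marker_logfc

    # Planted latent-factor modules: gene = baseline + loading * factor + noise.
    factors = rng.normal(0.0, 1.0, size=(design.n_cells, design.n_modules))
    for m in range(design.n_modules):
        rows = np.flatnonzero(module_of_gene == m + 1)
        log_mu[rows] += design.factor_loading * factors[:, m][None, :]

    if design.trajectory:
        # Smooth trend on a dedicated slice of background genes so cluster
        # centroids line up along the planted coordinate.
        n_traj = min(30, design.n_genes - pos) if pos < design.n_genes else 0
        traj_rows = np.arange(pos, pos + n_traj)
        slopes = rng.normal(0.0, 1.0, size=n_traj) * 3.0
        log_mu[traj_rows] += slopes[:, None] * (t - 0.5)[None, :]

    # Library sizes (log-normal, sigma fixed by design) scale each cell's means.
    lib = design.mean_library_size * np.exp(
        rng.normal(0.0, design.library_size_sigma, size=design.n_cells)
    )
    rel = np.exp(log_mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    # Gamma-Poisson mixture = negative binomial with var = mu + alpha mu^2.
    r = 1.0 / design.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    # Mito genes: overwrite so the per-cell mito fraction is controlled exactly.
    n_high = int(round(design.mito_high_cell_fraction * design.n_cells))
    high_cells = rng.permutation(design.n_cells)[:n_high]
    is_high = np.zeros(design.n_cells, dtype=bool)
    is_high[high_cells] = True
    mito_rows = np.arange(design.mito_gene_count)
    nonmito_total = counts.sum(axis=0) - counts[mito_rows].sum(axis=0)
    target = np.where(is_high, _MITO_HIGH_TARGET, _MITO_LOW_TARGET)
    mito_total = np.round(target / (1.0 - target) * nonmito_total).astype(np.int64)
    probs = np.full(design.mito_gene_count, 1.0 / design.mito_gene_count)
    for j in range(design.n_cells):
        counts[mito_rows, j] = rng.multinomial(mito_total[j], probs)

    values = pd.DataFrame(counts, index=genes, columns=cells)
    truth = SynthTruth(
        cluster_of_cell=pd.Series(cluster, index=cells),
        module_of_gene=pd.Series(module_of_gene, index=genes),
        factor_values=pd.DataFrame(
            factors, index=cells, columns=[f"M{m+1}" for m in range(design.n_modules)]
        ),
        pseudotime_truth=pseudotime_truth,
        marker_genes=marker_genes,
        mito_high_cells=[cells[i] for i in np.flatnonzero(is_high)],
    )
    return ExpressionMatrix(values, Unit.RAW_COUNTS), truth


def generate_fpkm(
    design: SynthDesign,
    n_expressed: int | None = None,
    n_groups: int = 1,
    group_shift_module: int | None = None,
    group_shift: float = 0.0,
) -> tuple[ExpressionMatrix, SynthTruth]:
    """Generate an FPKM-style continuous matrix with planted modules.

    ``n_expressed`` genes (module genes included, chosen from the front of
    the gene list) receive a high baseline so they pass the FPKM >= 5-in-5
    module-gene filter; the remaining genes are bounded below 5 and never
    pass.  If ``n_groups`` >= 2, cells are split into groups and the latent
    factor of ``group_shift_module`` is shifted by ``group_shift`` in every
    group beyond the first, planting a group-discriminative module.
    """
    rng = np.random.default_rng(design.seed)
    genes = _ids("gene", design.n_genes)
    cells = _ids("cm", design.n_cells)
    n_module_genes = design.n_modules * design.module_size
    if n_expressed is None:
        n_expressed = max(n_module_genes, design.n_genes // 2)
    if not n_module_genes <= n_expressed <= design.n_genes:
        raise ValueError("n_expressed must cover module genes and fit n_genes")

    module_of_gene = np.zeros(design.n_genes, dtype=int)
    pos = 0
    for m in range(design.n_modules):
        module_of_gene[pos : pos + design.module_size] = m + 1
        pos += design.module_size

    group = np.arange(design.n_cells) % max(n_groups, 1)
    factors = rng.normal(0.0, 1.0, size=(design.n_cells, design.n_modules))
    if group_shift_module is not None and group_shift != 0.0:
        factors[:, group_shift_module - 1] += group_shift * (group > 0)

    t = None
    values = np.empty((design.n_genes, design.n_cells))
    # Expressed genes: log-normal around FPKM ~ 30 plus module structure.
    log_base = np.log(30.0) + rng.normal(0.0, 0.4, size=n_expressed)
    log_vals = log_base[:, None] + rng.normal(0.0, 0.3, size=(n_expressed, design.n_cells))
    for m in range(design.n_modules):
        rows = np.flatnonzero(module_of_gene[:n_expressed] == m + 1)
        log_vals[rows] += design.factor_loading * factors[:, m][None, :]
    if design.trajectory:
        t = np.sort(rng.uniform(0.0, 1.0, size=design.n_cells))
        rng.shuffle(t)
        n_traj = min(30, n_expressed - n_module_genes)
        traj_rows = np.arange(n_module_genes, n_module_genes + n_traj)
        slopes = rng.normal(0.0, 1.0, size=n_traj) * 2.0
        log_vals[traj_rows] += slopes[:, None] * (t - 0.5)[None, :]
    values[:n_expressed] = np.exp(log_vals)
    # Silent genes: strictly below the floor of 5, so they never pass.
    values[n_expressed:] = rng.uniform(0.0, 4.5, size=(design.n_genes - n_expressed, design.n_cells))

    frame = pd.DataFrame(values, index=genes, columns=cells)
    truth = SynthTruth(
        module_of_gene=pd.Series(module_of_gene, index=genes),
        factor_values=pd.DataFrame(
            factors, index=cells, columns=[f"M{m+1}" for m in range(design.n_modules)]
        ),
        group_of_cell=pd.Series(group, index=cells) if n_groups >= 2 else None,
        expressed_genes=genes[:n_expressed],
        pseudotime_truth=pd.Series(t, index=cells) if t is not None else None,
    )
    return ExpressionMatrix(frame, Unit.FPKM), truth


def generate_tag_counts(
    n_singlets: int,
    n_doublets: int,
    n_zero: int,
    n_tags: int,
    signal_ratio: float,
    seed: int,
    ambient_mean: float = 10.0,
) -> tuple[TagCounts, SynthTruth]:
    """Generate a tag x barcode count matrix with known identities.

    Singlet barcodes draw their dominant tag at ``signal_ratio`` times the
    Poisson ambient background; doublets are exact sums of two singlet draws
    with distinct dominant tags; ``n_zero`` barcodes have all-zero counts.
    """
    if n_tags < 1:
        raise ValueError("n_tags must be >= 1")
    if n_doublets > 0 and n_tags < 2:
        raise ValueError("cross-tag doublets require n_tags >= 2")
    if signal_ratio <= 1:
        raise ValueError("signal_ratio must be > 1")
    rng = np.random.default_rng(seed)
    tags = [f"tag{t}" for t in range(n_tags)]

    def singlet_profile(dom: int) -> np.ndarray:
        prof = rng.poisson(ambient_mean, size=n_tags)
        prof[dom] = rng.poisson(signal_ratio * ambient_mean)
        return prof

    n_total = n_singlets + n_doublets + n_zero
    barcodes = _ids("BC", n_total)
    order = rng.permutation(n_total)
    counts = np.zeros((n_tags, n_total), dtype=np.int64)
    tag_of_barcode: dict[str, str] = {}
    doublet_set: set[str] = set()
    zero_set: set[str] = set()

    slot = 0
    for _ in range(n_singlets):
        bc = barcodes[order[slot]]
        dom = rng.integers(n_tags)
        counts[:, order[slot]] = singlet_profile(dom)
        tag_of_barcode[bc] = tags[dom]
        slot += 1
    for _ in range(n_doublets):
        bc = barcodes[order[slot]]
        d1, d2 = rng.choice(n_tags, size=2, replace=False)
        counts[:, order[slot]] = singlet_profile(d1) + singlet_profile(d2)
        doublet_set.add(bc)
        slot += 1
    for _ in range(n_zero):
        zero_set.add(barcodes[order[slot]])
        slot += 1

    frame = pd.DataFrame(counts, index=tags, columns=barcodes)
    truth = SynthTruth(
        doublet_barcodes=doublet_set,
        zero_barcodes=zero_set,
        tag_of_barcode=pd.Series(tag_of_barcode),
    )
    return TagCounts(frame), truth


def simulate_microwells(n_cells: int, n_wells: int, n_tags: int, seed: int) -> float:
    """Monte-Carlo oracle for the detectable-doublet fraction.

    Cells are thrown into wells uniformly at random and tagged uniformly;
    returns the fraction of occupied wells holding >= 2 cells with >= 2
    distinct tags.  Brute-force counterpart of the closed-form Poisson model.
    """
    if min(n_cells, n_wells, n_tags) < 1:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    wells = rng.integers(n_wells, size=n_cells)
    tags = rng.integers(n_tags, size=n_cells)
    occupied = np.unique(wells)
    # Distinct (well, tag) pairs; a well is a detectable doublet well when it
    # hosts at least two distinct tags.
    pair_wells = np.unique(wells.astype(np.int64) * n_tags + tags) // n_tags
    _, tag_div = np.unique(pair_wells, return_counts=True)
    detectable = int((tag_div >= 2).sum())
    return detectable / occupied.size


def mc_standard_error(fraction: float, n_occupied: int) -> float:
    """Binomial standard error of a Monte-Carlo occupied-well fraction."""
    return math.sqrt(max(fraction * (1.0 - fraction), 1e-12) / n_occupied)


def expected_occupied_wells(n_cells: int, n_wells: int) -> float:
    """Expected number of occupied wells under uniform random loading."""
    lam = n_cells / n_wells
    return n_wells * (1.0 - math.exp(-lam))
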