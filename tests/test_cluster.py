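"""PCA, permutation PC significance, graph clustering and marker tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cardiosc import cluster, qc, synth
from cardiosc.types import ExpressionMatrix, Unit
from conftest import blob_space


def scaled_from_array(arr):
    df = pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"c{j}" for j in range(arr.shape[1])],
    )
    sd = df.std(axis=1, ddof=1)
    df = df.sub(df.mean(axis=1), axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    return ExpressionMatrix(df, Unit.SCALED)


class TestPCA:
    def test_planted_factor_dominates_pc1(self):
        rng = np.random.default_rng(0)
        factor = rng.normal(size=200)
        arr = 2.0 * np.outer(rng.normal(size=50), factor) + rng.normal(
            size=(50, 200), scale=0.5
        )
        space = cluster.pca(scaled_from_array(arr), n_pcs=5)
        r = np.corrcoef(space.scores["PC1"], factor)[0, 1]
        assert abs(r) >= 0.9

    def test_variance_conservation(self):
        rng = np.random.default_rng(1)
        scaled = scaled_from_array(rng.normal(size=(40, 60)))
        space = cluster.pca(scaled, n_pcs=30)
        X = scaled.values.to_numpy().T
        total_var = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        assert space.variance_explained.sum() <= total_var + 1e-8
        assert (np.diff(space.variance_explained.to_numpy()) <= 1e-10).all()

    def test_duplicated_cells_give_identical_loadings(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(30, 50))
        base = scaled_from_array(arr)
        doubled = ExpressionMatrix(
            pd.concat(
                [base.values, base.values.add_suffix("_copy", axis=1)], axis=1
            ),
            Unit.SCALED,
        )
        s1 = cluster.pca(base, n_pcs=10)
        s2 = cluster.pca(doubled, n_pcs=10)
        np.testing.assert_allclose(
            s1.loadings.to_numpy(), s2.loadings.to_numpy(), atol=1e-8
        )

    def test_n_pcs_truncated_at_rank(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(10, 40))  # rank <= 10
        with pytest.warns(UserWarning, match="truncating"):
            space = cluster.pca(scaled_from_array(arr), n_pcs=30)
        assert space.scores.shape[1] <= 10

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        scaled = scaled_from_array(rng.normal(size=(25, 40)))
        s1 = cluster.pca(scaled, n_pcs=5)
        s2 = cluster.pca(scaled, n_pcs=5)
        pd.testing.assert_frame_equal(s1.loadings, s2.loadings)
        top = s1.loadings.abs().idxmax()
        for pc in s1.pc_names:
            assert s1.loadings.loc[top[pc], pc] > 0


class TestPermutationPCTest:
    def test_pure_noise_calibration(self):
        """Significant-PC count on noise stays near alpha * n_pcs."""
        total = 0
        n_seeds, n_pcs = 20, 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            scaled = scaled_from_array(rng.normal(size=(80, 60)))
            sig, _ = cluster.permutation_pc_test(
                scaled, n_pcs=n_pcs, n_replicates=30,
                perm_gene_fraction=0.05, seed=seed,
            )
            total += len(sig)
        expected = 0.05 * n_pcs * n_seeds
        assert total <= 3 * expected

    def test_planted_factor_pc1_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            factor = rng.normal(size=80)
            arr = 1.5 * np.outer(rng.normal(size=60), factor) + rng.normal(
                size=(60, 80)
            )
            sig, space = cluster.permutation_pc_test(
                scaled_from_array(arr), n_pcs=10, n_replicates=50,
                perm_gene_fraction=0.05, seed=seed,
            )
            if "PC1" in sig:
                hits += 1
        assert hits >= 19

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(5)
        sig, _ = cluster.permutation_pc_test(
            scaled_from_array(rng.normal(size=(40, 30))),
            n_pcs=5, n_replicates=10, perm_gene_fraction=0.1, alpha=0.0, seed=0,
        )
        assert sig == []

    def test_too_small_fraction_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            cluster.permutation_pc_test(
                scaled_from_array(rng.normal(size=(20, 30))),
                perm_gene_fraction=0.001, n_pcs=5, seed=0,
            )

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        scaled = scaled_from_array(rng.normal(size=(40, 50)))
        out1 = cluster.permutation_pc_test(
            scaled, n_pcs=8, n_replicates=20, perm_gene_fraction=0.05, seed=42
        )
        out2 = cluster.permutation_pc_test(
            scaled, n_pcs=8, n_replicates=20, perm_gene_fraction=0.05, seed=42
        )
        assert out1[0] == out2[0]
        pd.testing.assert_series_equal(out1[1].pc_pvalues, out2[1].pc_pvalues)


class TestGraphCluster:
    def test_two_separated_blobs_perfect_ari(self):
        space, truth = blob_space([[0, 0], [10, 0]], n_per=60, sd=1.0, seed=0)
        assign = cluster.graph_cluster(space, ["PC1", "PC2"], resolution=1.0, seed=0)
        assert adjusted_rand_score(truth, assign.cluster_of_cell) == 1.0

    def test_identical_cells_single_cluster(self):
        coords = np.zeros((30, 3))
        cells = [f"c{i}" for i in range(30)]
        space = cluster.ReducedSpace(
            scores=pd.DataFrame(coords, index=cells, columns=["PC1", "PC2", "PC3"]),
            loadings=pd.DataFrame(np.eye(3), columns=["PC1", "PC2", "PC3"]),
            variance_explained=pd.Series([0.0] * 3, index=["PC1", "PC2", "PC3"]),
        )
        assign = cluster.graph_cluster(space, ["PC1"], resolution=1.5, k_neighbors=10, seed=0)
        assert assign.cluster_of_cell.nunique() == 1

    def test_labels_contiguous_from_zero(self):
        space, _ = blob_space([[0, 0], [8, 0], [0, 8]], n_per=40, seed=1)
        assign = cluster.graph_cluster(space, ["PC1", "PC2"], resolution=1.5, seed=3)
        labels = sorted(assign.cluster_of_cell.unique())
        assert labels == list(range(len(labels)))

    def test_resolution_monotone_on_fixture(self):
        space, _ = blob_space([[0, 0], [6, 0], [0, 6], [6, 6]], n_per=40, seed=2)
        n = [
            cluster.graph_cluster(
                space, ["PC1", "PC2"], resolution=r, seed=0
            ).cluster_of_cell.nunique()
            for r in [0.5, 1.0, 1.5, 2.0]
        ]
        assert all(a <= b for a, b in zip(n, n[1:]))

    def test_seed_permutes_labels_only_on_separated_blobs(self):
        space, truth = blob_space([[0, 0], [12, 0], [0, 12]], n_per=40, seed=4)
        for seed in range(5):
            assign = cluster.graph_cluster(space, ["PC1", "PC2"], resolution=1.0, seed=seed)
            assert adjusted_rand_score(truth, assign.cluster_of_cell) == 1.0

    def test_k_neighbors_too_large_rejected(self):
        space, _ = blob_space([[0, 0]], n_per=10, seed=0)
        with pytest.raises(ValueError):
            cluster.graph_cluster(space, ["PC1"], k_neighbors=10, seed=0)


class TestFindMarkers:
    @staticmethod
    def planted_fixture(seed, ln_fc=2.0, n_genes=80, n_cells=120):
        """Two clusters; gene 0 shifted by ln_fc in cluster 0 with 80% detection."""
        mat, truth = synth.generate_counts(
            synth.SynthDesign(
                n_genes=n_genes, n_cells=n_cells, n_clusters=2,
                marker_logfc=ln_fc, n_modules=0, seed=seed,
            )
        )
        norm = qc.normalize_log(mat)
        assign = cluster.ClusterAssignment(truth.cluster_of_cell, 1.5, 20)
        return norm, assign, truth

    def test_planted_markers_recovered(self):
        hits = 0
        for seed in range(10):
            norm, assign, truth = self.planted_fixture(seed)
            table = cluster.find_markers(norm, assign)
            planted = set(truth.marker_genes[0]) | set(truth.marker_genes[1])
            found = set(table["gene"])
            if len(found & planted) >= len(planted) // 2:
                hits += 1
        assert hits >= 9

    def test_shuffled_labels_yield_no_markers(self):
        clean = 0
        for seed in range(20):
            norm, assign, _ = self.planted_fixture(seed, ln_fc=2.0)
            rng = np.random.default_rng(seed + 500)
            shuffled = pd.Series(
                rng.permutation(assign.cluster_of_cell.to_numpy()),
                index=assign.cluster_of_cell.index,
            )
            table = cluster.find_markers(
                norm, cluster.ClusterAssignment(shuffled, 1.5, 20)
            )
            if len(table) == 0:
                clean += 1
        assert clean >= 19

    def test_min_pct_gate_blocks_rare_genes(self):
        rng = np.random.default_rng(9)
        n_cells = 100
        vals = rng.uniform(0.5, 2.0, size=(20, n_cells))
        vals[0] = 0.0
        in_cells = np.arange(50)
        on = in_cells[:2]  # 4% of in-cluster cells -> below min.pct 0.1
        vals[0, on] = 5.0
        norm = ExpressionMatrix(pd.DataFrame(vals), Unit.LOG_NORM)
        labels = pd.Series(
            [0] * 50 + [1] * 50, index=norm.cell_ids
        )
        table = cluster.find_markers(
            norm, cluster.ClusterAssignment(labels, 1.5, 20)
        )
        assert "0" not in set(str(g) for g in table["gene"])

    def test_all_gates_hold_rowwise(self):
        norm, assign, _ = self.planted_fixture(3)
        table = cluster.find_markers(norm, assign)
        assert (table["log_fc"] >= 0.25).all()
        assert (table["pct_in"] >= 0.1).all()
        assert (table["p_bonferroni"] <= 0.05).all()
        assert (table["log_fc"] > 0).all()

    def test_tiny_cluster_skipped_with_warning(self):
        norm, assign, _ = self.planted_fixture(4)
        labels = assign.cluster_of_cell.copy()
        labels.iloc[:2] = 7  # cluster of size 2
        labels.iloc[2:] = np.where(np.arange(len(labels) - 2) % 2, 0, 1)
        with pytest.warns(UserWarning, match="fewer than 3"):
            cluster.find_markers(norm, cluster.ClusterAssignment(labels, 1.5, 20))

    def test_single_cluster_rejected(self):
        norm, assign, _ = self.planted_fixture(5)
        ones = pd.Series(0, index=assign.cluster_of_cell.index)
        with pytest.raises(ValueError):
            cluster.find_markers(norm, cluster.ClusterAssignment(ones, 1.5, 20))
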