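"""Filtering boundary semantics, normalization and scaling contracts."""

import numpy as np
import pandas as pd
import pytest

from cardiosc import qc, synth
from cardiosc.types import ExpressionMatrix, Unit


def counts_matrix(array, genes=None, cells=None):
    arr = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cells), Unit.RAW_COUNTS)


class TestFilterCellsGenes:
    def test_mito_fraction_boundary_is_strict(self):
        """A cell at mito fraction exactly 0.4 is retained; 0.41 is dropped."""
        genes = ["mt-0", "g1", "g2"]
        # cell totals 100; mito counts 40 (=0.4, keep) and 41 (>0.4, drop)
        mat = counts_matrix(
            [[40, 41], [30, 29], [30, 30]], genes=genes, cells=["keep", "drop"]
        )
        th = qc.QCThresholds(min_genes_per_cell=1, min_cells_per_gene=0)
        out, report = qc.filter_cells_genes(mat, th)
        assert list(out.cell_ids) == ["keep"]
        assert report.removed_by_rule["cell_mito_fraction"] == 1

    def test_toy_matrix_cell_then_gene_filter(self):
        """6x4 toy: cell detecting 1 gene dropped, then gene in 1 cell dropped."""
        arr = np.array(
            [
                [5, 4, 3, 0],
                [2, 1, 2, 0],
                [1, 3, 1, 0],
                [0, 2, 2, 0],
                [4, 0, 1, 0],
                [0, 0, 2, 9],  # only detected in c2 after c3 is dropped
            ]
        )
        mat = counts_matrix(arr)
        th = qc.QCThresholds(
            min_genes_per_cell=2, min_cells_per_gene=2, max_mito_fraction=1.0
        )
        out, report = qc.filter_cells_genes(mat, th)
        assert out.values.shape == (5, 3)
        assert "c3" not in out.cell_ids  # detected only 1 gene
        assert "g5" not in out.gene_ids  # present in 1 surviving cell
        assert report.cells_in - report.cells_out == 1

    def test_zero_thresholds_are_identity(self):
        mat = counts_matrix(np.arange(12).reshape(3, 4))
        th = qc.QCThresholds(
            min_genes_per_cell=0, min_cells_per_gene=0, max_mito_fraction=1.0
        )
        out, _ = qc.filter_cells_genes(mat, th)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_filter_is_idempotent(self):
        mat, _ = synth.generate_counts(
            synth.SynthDesign(n_genes=100, n_cells=150, mito_high_cell_fraction=0.1, seed=4)
        )
        th = qc.QCThresholds(min_genes_per_cell=30)
        once, _ = qc.filter_cells_genes(mat, th)
        twice, _ = qc.filter_cells_genes(once, th)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_explicit_mito_list_overrides_prefix(self):
        mat = counts_matrix([[70, 10], [30, 90]], genes=["mt-0", "other"])
        th = qc.QCThresholds(min_genes_per_cell=0, min_cells_per_gene=0)
        # declare "other" mitochondrial: second cell is 90% mito -> dropped,
        # first is 30% (the mt- prefixed gene no longer counts)
        _, report = qc.filter_cells_genes(mat, th, mito_genes=["other"])
        assert report.removed_by_rule["cell_mito_fraction"] == 1
        assert report.per_cell["mito_fraction"].tolist() == [0.3, 0.9]


class TestCardiomyocyteFilters:
    def test_detected_gene_boundary_inclusive(self):
        """Exactly 3,000 detected genes is retained ('less than 3,000' drops)."""
        n_genes = 3200
        vals = np.zeros((n_genes, 3))
        vals[:3000, 0] = 1.0  # exactly 3000 detected -> kept
        vals[:2999, 1] = 1.0  # 2999 -> dropped
        vals[:3100, 2] = 1.0  # kept
        mat = ExpressionMatrix(
            pd.DataFrame(vals, columns=["at", "below", "above"]), Unit.FPKM
        )
        out = qc.filter_cardiomyocytes(mat)
        assert list(out.cell_ids) == ["at", "above"]

    def test_all_cells_empty_reports_not_raises(self):
        mat = ExpressionMatrix(pd.DataFrame(np.zeros((10, 4))), Unit.FPKM)
        with pytest.warns(UserWarning):
            out = qc.filter_cardiomyocytes(mat, min_detected=1)
        assert out.n_cells == 0

    def test_synthetic_fixture_counted(self):
        rng = np.random.default_rng(8)
        n_genes = 4000
        detected = [3500] * 7 + [1000, 2999, 0]
        vals = np.zeros((n_genes, 10))
        for j, d in enumerate(detected):
            on = rng.choice(n_genes, size=d, replace=False)
            vals[on, j] = rng.uniform(1, 50, size=d)
        mat = ExpressionMatrix(pd.DataFrame(vals), Unit.FPKM)
        assert qc.filter_cardiomyocytes(mat).n_cells == 7


class TestFpkmModuleGeneFilter:
    def test_inclusive_boundaries(self):
        """FPKM exactly 5 in exactly 5 cells passes; 4.99 everywhere fails."""
        vals = np.zeros((2, 8))
        vals[0, :5] = 5.0
        vals[1, :] = 4.99
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=["at_boundary", "below"]), Unit.FPKM
        )
        assert qc.fpkm_module_gene_filter(mat) == ["at_boundary"]

    def test_planted_passing_genes_counted(self):
        design = synth.SynthDesign(
            n_genes=100, n_cells=60, n_modules=1, module_size=30, seed=12
        )
        mat, truth = synth.generate_fpkm(design, n_expressed=37)
        kept = qc.fpkm_module_gene_filter(mat)
        assert len(kept) == 37
        assert set(kept) == set(truth.expressed_genes)


class TestNormalizeLog:
    def test_zero_stays_zero_and_known_value(self):
        mat = counts_matrix([[1], [999_999]])
        out = qc.normalize_log(mat)
        # count 1 in a 1e6-total cell -> ln(1 * 1e6/1e6 + 1) = ln 2
        assert out.values.iloc[0, 0] == pytest.approx(np.log(2), abs=1e-12)
        zero = counts_matrix([[0, 3], [5, 2]])
        assert qc.normalize_log(zero).values.iloc[0, 0] == 0.0

    def test_depth_invariance_and_monotonicity(self):
        mat = counts_matrix([[3, 6], [7, 14], [0, 0], [10, 20]])
        out = qc.normalize_log(mat)
        np.testing.assert_allclose(
            out.values.iloc[:, 0], out.values.iloc[:, 1], atol=1e-12
        )
        # within-cell ranking preserved
        col = out.values.iloc[:, 0]
        raw = mat.values.iloc[:, 0]
        assert (col.rank() == raw.rank()).all()

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            qc.normalize_log(counts_matrix([[0, 1], [0, 2]]))


class TestSelectVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 2.0, size=(20, 50))
        vals[0] = 1.3
        mat = ExpressionMatrix(pd.DataFrame(vals), Unit.LOG_NORM)
        assert "0" not in [str(g) for g in qc.select_variable_genes(mat, y_cutoff=-10)]

    def test_low_mean_gene_excluded_regardless_of_dispersion(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1.0, 2.0, size=(30, 80))
        vals[0] = rng.choice([0.0, 0.09], size=80)  # wildly dispersed, tiny mean
        mat = ExpressionMatrix(pd.DataFrame(vals), Unit.LOG_NORM)
        selected = qc.select_variable_genes(mat, x_low=0.1, y_cutoff=0.5)
        assert "0" not in [str(g) for g in selected]

    def test_planted_overdispersed_gene_selected(self):
        """A gene with 10x the baseline NB dispersion is picked in >=9/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_genes, n_cells, mean = 100, 300, 50.0
            r_base, r_od = 1 / 0.1, 1 / 1.0
            counts = rng.poisson(rng.gamma(r_base, mean / r_base, (n_genes, n_cells)))
            counts[0] = rng.poisson(rng.gamma(r_od, mean / r_od, n_cells))
            mat = ExpressionMatrix(
                pd.DataFrame(counts.astype(np.int64)), Unit.RAW_COUNTS
            )
            norm = qc.normalize_log(mat)
            if "0" in [str(g) for g in qc.select_variable_genes(norm)]:
                hits += 1
        assert hits >= 9


class TestScaleAndRegress:
    @pytest.fixture()
    def norm(self):
        mat, _ = synth.generate_counts(
            synth.SynthDesign(n_genes=80, n_cells=100, seed=21)
        )
        return qc.normalize_log(mat)

    def test_rows_standardized(self, norm):
        scaled = qc.scale_and_regress(norm)
        arr = scaled.values.to_numpy()
        live = arr.std(axis=1) > 0
        np.testing.assert_allclose(arr[live].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(arr[live].std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_covariate_regressed_out(self, norm):
        covariate = norm.values.sum(axis=0).to_numpy() + np.linspace(0, 5, norm.n_cells)
        scaled = qc.scale_and_regress(norm, covariate)
        arr = scaled.values.to_numpy()
        c = covariate - covariate.mean()
        for row in arr[arr.std(axis=1) > 0]:
            r = np.dot(row, c) / np.sqrt(np.dot(row, row) * np.dot(c, c))
            assert abs(r) < 1e-10

    def test_gene_proportional_to_covariate_becomes_zero(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = pd.DataFrame([2.0 * cov + 1.0, [0.1, 0.5, 0.2, 0.9, 0.4]])
        mat = ExpressionMatrix(vals, Unit.LOG_NORM)
        scaled = qc.scale_and_regress(mat, cov)
        np.testing.assert_allclose(scaled.values.iloc[0], 0.0, atol=1e-10)
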