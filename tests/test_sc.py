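"""QC, normalization, HVG, clustering grid, cell cycle, lineage, DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from ticp.sc import (DIMS_GRID_DEFAULT, QCConfig, assign_lineage,
                     default_lineage_sets, differential_expression,
                     lognormalize, qc_filter, reduce_and_cluster,
                     score_cell_cycle, select_hvg)
from ticp.simulate import CountMatrix, ScSimConfig, generate_sc_cohort


def toy_matrix(counts: np.ndarray, genes=None, patient="T") -> CountMatrix:
    n, g = counts.shape
    genes = genes or [f"G{i}" for i in range(g)]
    return CountMatrix(
        patient=patient,
        counts=sparse.csr_matrix(counts.astype(np.int64)),
        barcodes=[f"BC{i}" for i in range(n)],
        genes=genes,
    )


class TestQC:
    def test_exact_threshold_behaviour(self):
        """Each of the four printed cutoffs removes exactly its violators."""
        q = QCConfig(min_cells_per_gene=5, min_umi=1000, min_genes=2,
                     max_mito_frac=0.20)
        counts = np.zeros((8, 4), dtype=int)
        counts[:, 0] = 600  # gene A: ubiquitous
        counts[:, 1] = 500  # gene B: ubiquitous
        counts[:4, 2] = 1   # gene C: detected in 4 < 5 cells → removed
        counts[:, 3] = 10   # MT gene, detected everywhere
        counts[0, 1] = 389  # cell 0: 600+389+10 = 999 UMIs → removed
        counts[1, 3] = 400  # cell 1: 400/1500 = 26.7% mito → removed
        m = toy_matrix(counts, genes=["A", "B", "C", "MT-X"])
        filtered, report = qc_filter(m, q)
        assert report.genes_removed_low_cells == 1  # gene C only
        assert "C" not in filtered.genes
        assert report.cells_removed_low_umi == 1
        assert report.cells_removed_high_mito == 1
        assert report.cells_removed_low_genes == 0
        assert filtered.counts.shape[0] == 6

    def test_low_gene_count_cell_removed(self):
        q = QCConfig(min_cells_per_gene=1, min_umi=10, min_genes=3,
                     max_mito_frac=0.5)
        counts = np.full((4, 3), 50, dtype=int)
        counts[0, 1:] = 0  # cell 0 detects 1 gene
        filtered, report = qc_filter(toy_matrix(counts), q)
        assert report.cells_removed_low_genes == 1
        assert filtered.counts.shape[0] == 3

    def test_clean_matrix_unchanged_and_idempotent(self, sc_patient):
        filtered = sc_patient["filtered"]
        again, report = qc_filter(filtered)
        assert report.n_cells_out == filtered.counts.shape[0]
        assert again.genes == filtered.genes
        assert (again.counts != filtered.counts).nnz == 0

    def test_all_filtered_is_error(self):
        q = QCConfig(min_cells_per_gene=1, min_umi=10_000, min_genes=1,
                     max_mito_frac=0.99)
        with pytest.raises(ValueError, match="QC removed everything"):
            qc_filter(toy_matrix(np.full((3, 3), 5)), q)


class TestLogNormalize:
    def test_formula(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [100, 9900, 0]
        norm = lognormalize(toy_matrix(counts), scale=10_000)
        x = np.asarray(norm.values.todense())
        assert x[0, 0] == pytest.approx(np.log(101))
        assert x[0, 2] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[10, 20, 30], [20, 40, 60]])
        norm = lognormalize(toy_matrix(counts))
        x = np.asarray(norm.values.todense())
        assert x[0] == pytest.approx(x[1])

    def test_zero_total_cell_rejected(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError):
            lognormalize(toy_matrix(counts))


class TestHVG:
    def test_constant_gene_never_selected(self, rng):
        counts = rng.poisson(5.0, size=(200, 20))
        counts[:, 0] = 7  # constant
        got = select_hvg(toy_matrix(counts), n=19)
        assert "G0" not in got

    def test_requesting_too_many_returns_all(self, rng, caplog):
        counts = rng.poisson(2.0, size=(50, 10))
        got = select_hvg(toy_matrix(counts), n=3000)
        assert len(got) == 10

    def test_planted_overdispersed_genes_rank_high(self):
        cfg = ScSimConfig(
            n_patients=1, cells_per_patient=1500, seed=31,
            gene_dispersion={f"GENE{i:04d}": 0.2 for i in range(1, 21)},
        )
        cm, _, _ = generate_sc_cohort(cfg)[0]
        n_top = len(cm.genes) // 10
        top = set(select_hvg(cm, n=n_top))
        planted = {f"GENE{i:04d}" for i in range(1, 21)}
        assert len(planted & top) >= 15  # vast majority in the top decile


class TestClusterGrid:
    def test_default_dims_grid_spans_24_candidates(self):
        assert list(DIMS_GRID_DEFAULT) == list(range(3, 50, 2))
        assert len(DIMS_GRID_DEFAULT) == 24

    def test_three_planted_clusters_recovered(self):
        cfg = ScSimConfig(
            n_patients=1, cells_per_patient=1200, seed=17,
            cluster_props={"CD8_EM": 0.4, "CD4_EM": 0.35, "TREG": 0.25},
        )
        cm, _, truth = generate_sc_cohort(cfg)[0]
        filtered, _ = qc_filter(cm)
        norm = lognormalize(filtered)
        hvg = select_hvg(filtered, n=3000)
        res = reduce_and_cluster(
            norm, hvg, dims_grid=(5, 9, 13), res_grid=(0.2, 0.4, 0.6), seed=0
        )
        tr = truth.cells.set_index("barcode").reindex(norm.barcodes)
        assert adjusted_rand_score(tr["cluster"], res.labels) >= 0.9

    def test_oversized_dims_dropped_with_report_intact(self, rng):
        counts = rng.poisson(3.0, size=(60, 30))
        norm = lognormalize(toy_matrix(counts))
        res = reduce_and_cluster(
            norm, [f"G{i}" for i in range(30)],
            dims_grid=(5, 100), res_grid=(0.5, 1.0), seed=0,
        )
        assert set(res.report["dims"]) == {5}


class TestCellCycle:
    def test_all_zero_cell_called_g1(self, rng):
        counts = rng.poisson(3.0, size=(50, 40))
        counts[0] = 0
        counts[0, 39] = 1  # one count outside both sets keeps the total > 0
        norm = lognormalize(toy_matrix(counts))
        s = [f"G{i}" for i in range(5)]
        g2m = [f"G{i}" for i in range(5, 10)]
        scores = score_cell_cycle(norm, s, g2m, seed=0)
        assert scores.iloc[0]["phase"] == "G1"

    def test_planted_g2m_program_recovered(self):
        cfg = ScSimConfig(
            n_patients=1, cells_per_patient=1000, seed=23,
            cluster_props={"CD4_EM": 0.7, "CYCLING": 0.3},
            cluster_lineage={"CD4_EM": "CD4", "CYCLING": "CD4"},
            marker_programs={
                "CD4_EM": {"CD4": 6.0, "IL7R": 6.0},
                "CYCLING": {"CD4": 6.0, "HMGB2": 5.5, "CDK1": 5.5,
                            "NUSAP1": 5.5, "UBE2C": 5.5, "BIRC5": 5.5,
                            "TPX2": 5.5},
            },
        )
        cm, _, truth = generate_sc_cohort(cfg)[0]
        filtered, _ = qc_filter(cm)
        norm = lognormalize(filtered)
        scores = score_cell_cycle(norm, seed=0)
        tr = truth.cells.set_index("barcode").reindex(norm.barcodes)
        planted = tr["cluster"] == "CYCLING"
        assert (scores.loc[planted.to_numpy(), "phase"] == "G2M").mean() >= 0.95

    def test_deterministic_given_seed(self, sc_patient):
        norm = sc_patient["norm"]
        a = score_cell_cycle(norm, seed=5)
        b = score_cell_cycle(norm, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_sets_rejected(self, sc_patient):
        with pytest.raises(ValueError, match="none of the score genes"):
            score_cell_cycle(sc_patient["norm"], ["NOPE1"], ["NOPE2"], seed=0)


class TestLineage:
    def test_cd8_only_cluster_labeled_cd8(self, rng):
        genes = ["CD8A", "CD8B", "CD4", "IL7R", "FOXP3", "IL2RA", "HK1"]
        counts = rng.poisson(1.0, size=(60, 7))
        counts[:, 4:6] = 0  # FOXP3/IL2RA silent everywhere
        counts[:, 6] += 20  # housekeeping keeps totals positive
        counts[:30, 0:2] += 30  # cluster 0: CD8A/CD8B only
        counts[30:, 2:4] += 30  # cluster 1: CD4/IL7R
        norm = lognormalize(toy_matrix(counts, genes=genes))
        labels = np.repeat([0, 1], 30)
        out = assign_lineage(labels, norm)
        assert out[0] == "CD8" and out[1] == "CD4"

    def test_exactly_one_treg_cluster_in_default_cohort(self, sc_patient):
        truth = sc_patient["truth_cells"]
        norm = sc_patient["norm"]
        codes = pd.Categorical(truth["cluster"]).codes
        out = assign_lineage(codes, norm)
        cats = pd.Categorical(truth["cluster"]).categories
        assert sum(v == "Treg" for v in out.values()) == 1
        treg_code = [c for c, v in out.items() if v == "Treg"][0]
        assert cats[treg_code] == "TREG"

    def test_foxp3_detection_gate_blocks_spurious_treg(self, rng):
        # IL2RA high but FOXP3 absent → falls back to next-best lineage
        genes = ["CD8A", "CD8B", "CD4", "IL7R", "FOXP3", "IL2RA", "HK1"]
        counts = rng.poisson(1.0, size=(40, 7))
        counts[:, 6] += 20
        counts[:, 5] += 40  # IL2RA
        counts[:, 2] += 10  # CD4
        counts[:, 4] = 0  # FOXP3 never detected
        norm = lognormalize(toy_matrix(counts, genes=genes))
        out = assign_lineage(np.zeros(40, dtype=int), norm)
        assert out[0] != "Treg"


class TestDifferentialExpression:
    def test_identical_groups_empty(self, rng):
        counts = rng.poisson(2.0, size=(30, 15)) + 1
        counts = np.vstack([counts, counts])  # two identical blocks
        norm = lognormalize(toy_matrix(counts))
        res = differential_expression(norm, np.arange(30), np.arange(30, 60))
        assert len(res) == 0

    def test_overlapping_groups_rejected(self, sc_patient):
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(sc_patient["norm"], np.arange(10),
                                    np.arange(5, 15))

    def test_planted_fold_change_recovered_with_sign(self, rng):
        counts = rng.poisson(3.0, size=(100, 20)) + 1
        counts[:50, 0] *= 4  # 4-fold up in group A
        norm = lognormalize(toy_matrix(counts))
        res = differential_expression(norm, np.arange(50), np.arange(50, 100))
        assert "G0" in set(res["gene"])
        assert res.set_index("gene").loc["G0", "avg_log2FC"] > 0
        flipped = differential_expression(norm, np.arange(50, 100), np.arange(50))
        assert flipped.set_index("gene").loc["G0", "avg_log2FC"] < 0

    def test_antisymmetry(self, sc_patient):
        norm = sc_patient["norm"]
        truth = sc_patient["truth_cells"]
        a = np.flatnonzero((truth["cluster"] == "TREG").to_numpy())
        b = np.flatnonzero((truth["cluster"] == "CD4_EM").to_numpy())
        ab = differential_expression(norm, a, b)
        ba = differential_expression(norm, b, a)
        merged = ab.set_index("gene").join(ba.set_index("gene"),
                                           lsuffix="_ab", rsuffix="_ba")
        assert len(merged) > 0
        assert merged["avg_log2FC_ab"].to_numpy() == pytest.approx(
            -merged["avg_log2FC_ba"].to_numpy()
        )
        assert merged["p_val_ab"].to_numpy() == pytest.approx(
            merged["p_val_ba"].to_numpy()
        )

    def test_output_respects_all_filters(self, sc_patient):
        norm = sc_patient["norm"]
        truth = sc_patient["truth_cells"]
        a = np.flatnonzero((truth["cluster"] == "TREG").to_numpy())
        b = np.flatnonzero((truth["cluster"] == "CD8_EX").to_numpy())
        res = differential_expression(norm, a, b)
        assert len(res) > 0
        assert (res["avg_log2FC"].abs() >= 0.58).all()
        assert (res[["pct.1", "pct.2"]].max(axis=1) >= 0.25).all()
        assert (res["p_val_adj"] < 0.05).all()

    def test_log2fc_threshold_is_1p5_fold(self):
        assert 2**0.58 == pytest.approx(1.5, abs=0.01)
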