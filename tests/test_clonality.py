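"""Clonality × checkpoint-expression compartments, burden, fold-change maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ticp.clonality import (ICPPanel, PatientCells, classify_expression,
                            compartmentalize, icp_burden, icp_medians,
                            lc_hc_differential)
from ticp.sc import lognormalize, qc_filter
from ticp.simulate import ScSimConfig, generate_sc_cohort
from ticp.tcr import ClonotypeTable, call_clonotypes, size_class

PANEL = ICPPanel()


def build_patient(cm, contigs, truth, patient="P1"):
    filtered, _ = qc_filter(cm)
    norm = lognormalize(filtered)
    table = call_clonotypes(contigs, patient, barcodes=norm.barcodes)
    tr = truth.cells.set_index("barcode").reindex(norm.barcodes)
    return PatientCells(norm=norm, clonotypes=table, clusters=tr["cluster"]), tr


@pytest.fixture(scope="module")
def default_patient():
    cfg = ScSimConfig(n_patients=1, cells_per_patient=6000, seed=303)
    cm, contigs, truth = generate_sc_cohort(cfg)[0]
    return build_patient(cm, contigs, truth)


def toy_patient(values: np.ndarray, counts: np.ndarray, clonality: list[str],
                clusters: list[str], patient="P1"):
    """Hand-built patient over the 10 panel genes."""
    from ticp.sc import NormMatrix

    n = len(values)
    barcodes = [f"c{i}" for i in range(n)]
    norm = NormMatrix(
        patient=patient,
        values=sparse.csr_matrix(values.astype(float)),
        counts=sparse.csr_matrix(counts.astype(np.int64)),
        barcodes=barcodes,
        genes=PANEL.genes,
    )
    rows = []
    for i, cl in enumerate(clonality):
        size = {"HC": 3, "LC": 1, "none": 0}[cl]
        rows.append({"barcode": barcodes[i],
                     "clonotype_id": f"{patient}_ct{i}" if cl != "none" else None,
                     "n_productive_chains": 2 if cl != "none" else 0,
                     "clone_size": size, "clonality": cl,
                     "size_class": size_class(size) if size else None})
    table = ClonotypeTable(patient=patient, cells=pd.DataFrame(rows))
    return PatientCells(norm=norm, clonotypes=table,
                        clusters=pd.Series(clusters, index=barcodes))


class TestMedians:
    def test_sparse_majority_gives_zero_median(self, default_patient):
        patient, _ = default_patient
        med = icp_medians([patient], PANEL)
        # checkpoint genes are silent in most cells of a mixed cohort
        assert (med.loc["P1"] == 0).sum() >= 8

    def test_hand_values(self):
        values = np.zeros((3, 10))
        values[:, 0] = [0.0, 1.0, 2.0]
        p = toy_patient(values, values > 0, ["LC"] * 3, ["K"] * 3)
        med = icp_medians([p], PANEL)
        assert med.loc["P1", "IL2RA"] == 1.0
        assert (med.loc["P1"].drop("IL2RA") == 0).all()

    def test_invariant_to_cell_order(self, default_patient):
        patient, _ = default_patient
        med = icp_medians([patient], PANEL)
        order = np.random.default_rng(0).permutation(len(patient.norm.barcodes))
        norm = patient.norm
        from ticp.sc import NormMatrix
        shuffled = NormMatrix(
            patient="P1",
            values=norm.values[order],
            counts=norm.counts[order],
            barcodes=[norm.barcodes[i] for i in order],
            genes=norm.genes,
        )
        cells = patient.clonotypes.cells.set_index("barcode")
        table = ClonotypeTable(
            patient="P1",
            cells=cells.loc[shuffled.barcodes].reset_index(),
        )
        p2 = PatientCells(norm=shuffled, clonotypes=table,
                          clusters=patient.clusters)
        med2 = icp_medians([p2], PANEL)
        pd.testing.assert_frame_equal(med, med2)


class TestClassifyExpression:
    def test_detection_majority_when_medians_zero(self):
        values = np.zeros((3, 10))
        values[0, :6] = 1.0  # 6 of 10 panel genes detected → HE
        p = toy_patient(values, values > 0, ["LC"] * 3, ["K"] * 3)
        med = icp_medians([p], PANEL)
        assert (med.loc["P1"] == 0).all()  # zeros hold the majority
        expr = classify_expression([p], med, PANEL)["P1"]
        assert expr["c0"] == "HE"
        assert expr["c1"] == "LE"  # zero checkpoint expression

    def test_planted_high_icp_cells_recovered(self, default_patient):
        patient, truth = default_patient
        med = icp_medians([patient], PANEL)
        expr = classify_expression([patient], med, PANEL)["P1"]
        treg = (truth["cluster"] == "TREG").to_numpy()
        clonotyped = truth["clonotype_id"].notna().to_numpy()
        assert (expr.to_numpy()[treg & clonotyped] == "HE").mean() >= 0.95
        background = (truth["cluster"] == "CD4_EM").to_numpy()
        assert (expr.to_numpy()[background & clonotyped] == "LE").mean() >= 0.90

    def test_unclonotyped_cells_unlabeled(self, default_patient):
        patient, truth = default_patient
        med = icp_medians([patient], PANEL)
        expr = classify_expression([patient], med, PANEL)["P1"]
        no_tcr = truth["clonotype_id"].isna().to_numpy()
        assert expr.to_numpy()[no_tcr] == pytest.approx(None) or \
            pd.isna(expr.to_numpy()[no_tcr]).all()


class TestCompartments:
    def test_joint_label_definition_and_sums(self):
        values = np.zeros((4, 10))
        values[0, :6] = 1.0  # HC + HE
        values[2, :6] = 1.0  # LC + HE
        p = toy_patient(values, values > 0, ["HC", "HC", "LC", "LC"],
                        ["K"] * 4)
        med = icp_medians([p], PANEL)
        expr = classify_expression([p], med, PANEL)
        cells, comp = compartmentalize([p], expr)
        got = cells.set_index("barcode")["compartment"]
        assert got.tolist() == ["HC_HE", "HC_LE", "LC_HE", "LC_LE"]
        assert comp.loc["K"].sum() == pytest.approx(100.0)

    def test_partition_property_on_cohort(self, default_patient):
        patient, truth = default_patient
        med = icp_medians([patient], PANEL)
        expr = classify_expression([patient], med, PANEL)
        cells, comp = compartmentalize([patient], expr)
        assert len(cells) == truth["clonotype_id"].notna().sum()
        assert np.allclose(comp.sum(axis=1), 100.0)

    def test_planted_association_concentrates_hc_he_in_treg(self, default_patient):
        patient, truth = default_patient
        med = icp_medians([patient], PANEL)
        expr = classify_expression([patient], med, PANEL)
        cells, comp = compartmentalize([patient], expr, treg_cluster="TREG")
        cd4 = cells[cells["cluster"].isin(["CD4_EM", "TREG"])]
        hc_he = cd4[cd4["compartment"] == "HC_HE"]
        assert len(hc_he) > 20
        assert (hc_he["cluster"] == "TREG").mean() >= 0.75


class TestBurden:
    def test_counts_detected_panel_genes(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, [0, 4, 5]] = 3  # IL2RA, CTLA4, ICOS
        p = toy_patient(np.log1p(counts), counts, ["HC", "LC"], ["K", "K"])
        cells, _ = icp_burden([p], PANEL)
        assert cells.set_index("barcode").loc["c0", "burden"] == 3
        assert cells.set_index("barcode").loc["c1", "burden"] == 0

    def test_bounded_by_panel_size(self, default_patient):
        patient, _ = default_patient
        cells, _ = icp_burden([patient], PANEL)
        assert cells["burden"].between(0, 10).all()

    def test_planted_burden_shift_recovered(self):
        """Expansion-linked boost sized to raise Treg burden by ≈1 checkpoint."""
        programs = {
            "CD4_EM": {"CD4": 6.0, "IL7R": 6.0},
            "TREG": {"CD4": 6.0, "FOXP3": 7.0,
                     **{g: 1.0 for g in PANEL.genes}},
        }
        effect = 0.72
        cfg = ScSimConfig(
            n_patients=1, cells_per_patient=2000, seed=41,
            cluster_props={"CD4_EM": 0.5, "TREG": 0.5},
            cluster_lineage={"CD4_EM": "CD4", "TREG": "CD4"},
            marker_programs=programs,
            planted_icp_effect=effect,
            library_size_sigma=0.0,
            clone_size_law={"CD4": 0.5},
        )
        # expected detection shift per NB gene: p(mu) = mu/(1+mu) at theta=1
        mu = cfg.icp_base_mean * 2.0  # panel genes carry a +1 log2 program
        expected = 10 * (mu * 2**effect / (1 + mu * 2**effect) - mu / (1 + mu))
        assert expected == pytest.approx(1.0, abs=0.05)

        cm, contigs, truth = generate_sc_cohort(cfg)[0]
        patient, tr = build_patient(cm, contigs, truth)
        cells, _ = icp_burden([patient], PANEL)
        treg = cells[(tr["cluster"] == "TREG").to_numpy()]
        hc = treg.loc[treg["clonality"] == "HC", "burden"]
        lc = treg.loc[treg["clonality"] == "LC", "burden"]
        assert hc.mean() - lc.mean() == pytest.approx(expected, abs=0.2)


class TestLcHcDifferential:
    def test_identical_expression_gives_zero(self):
        values = np.tile(np.linspace(0, 1, 10), (40, 1))
        p = toy_patient(values, values > 0,
                        ["HC"] * 20 + ["LC"] * 20, ["K"] * 40)
        diff = lc_hc_differential([p], PANEL)
        assert np.allclose(diff.loc["K"].to_numpy(), 0.0)

    def test_cluster_without_lc_cells_missing(self):
        values = np.zeros((30, 10))
        p = toy_patient(values, values > 0, ["HC"] * 30, ["K"] * 30)
        diff = lc_hc_differential([p], PANEL)
        assert diff.empty or "K" not in diff.index

    def test_planted_treg_enrichment_recovered(self, default_patient):
        patient, _ = default_patient
        diff = lc_hc_differential([patient], PANEL)
        # planted +1 log2 on checkpoint genes in expanded regulatory clones
        treg_row = diff.loc["TREG", ["ENTPD1", "IL2RA", "CTLA4", "ICOS"]]
        assert treg_row.mean() == pytest.approx(1.0, abs=0.3)
        null_rows = diff.drop(index="TREG")
        assert np.nanmax(np.abs(null_rows.to_numpy())) < 0.6


class TestReorderingInvariance:
    def test_outputs_invariant_under_patient_reordering(self):
        cfg = ScSimConfig(n_patients=2, cells_per_patient=800, seed=55)
        cohort = generate_sc_cohort(cfg)
        patients = [build_patient(cm, contigs, truth, patient=cm.patient)[0]
                    for cm, contigs, truth in cohort]
        med_ab = icp_medians(patients, PANEL)
        med_ba = icp_medians(patients[::-1], PANEL)
        pd.testing.assert_frame_equal(med_ab.sort_index(), med_ba.sort_index())
        diff_ab = lc_hc_differential(patients, PANEL)
        diff_ba = lc_hc_differential(patients[::-1], PANEL)
        pd.testing.assert_frame_equal(diff_ab.sort_index(), diff_ba.sort_index())
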