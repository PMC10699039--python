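"""Clonotype calling, repertoire metrics, and cross-cluster sharing."""

import numpy as np
import pandas as pd
import pytest

from ticp.simulate import ScSimConfig, generate_sc_cohort
from ticp.tcr import (SIZE_CLASSES, call_clonotypes, clonotype_sharing,
                      repertoire_metrics, size_class)


def contig(bc, chain, v, j, nt, productive="True"):
    return {"barcode": bc, "chain": chain, "v_gene": v, "j_gene": j,
            "cdr3": "CASSF", "cdr3_nt": nt, "productive": productive}


def make_contigs(rows):
    return pd.DataFrame(rows)


PAIR = [("TRA", "TRAV1", "TRAJ4", "TGTGCA"), ("TRB", "TRBV2", "TRBJ1-1", "TGTGCC")]


def paired_cell(bc):
    return [contig(bc, *PAIR[0]), contig(bc, *PAIR[1])]


class TestCallClonotypes:
    def test_identical_pairs_share_id_and_are_lc(self):
        contigs = make_contigs(paired_cell("c1") + paired_cell("c2"))
        table = call_clonotypes(contigs, "P1")
        cells = table.cells.set_index("barcode")
        assert cells.loc["c1", "clonotype_id"] == cells.loc["c2", "clonotype_id"]
        assert cells.loc["c1", "clone_size"] == 2
        assert (cells["clonality"] == "LC").all()

    def test_three_cells_are_hc(self):
        contigs = make_contigs(sum((paired_cell(f"c{i}") for i in range(3)), []))
        table = call_clonotypes(contigs, "P1")
        assert (table.cells["clonality"] == "HC").all()
        assert (table.cells["size_class"] == "3-10").all()

    def test_single_shared_chain_is_distinct_clonotype(self):
        # c2 carries only the beta chain of c1's pair → strict key differs
        contigs = make_contigs(paired_cell("c1") + [contig("c2", *PAIR[1])])
        table = call_clonotypes(contigs, "P1")
        cells = table.cells.set_index("barcode")
        assert cells.loc["c1", "clonotype_id"] != cells.loc["c2", "clonotype_id"]

    def test_non_productive_cells_unassigned(self):
        contigs = make_contigs(
            [contig("c1", *PAIR[0], productive="False")] + paired_cell("c2")
        )
        table = call_clonotypes(contigs, "P1", barcodes=["c1", "c2", "c3"])
        cells = table.cells.set_index("barcode")
        assert cells.loc["c1", "clonality"] == "none"
        assert cells.loc["c3", "clonality"] == "none"  # no contigs at all
        assert cells.loc["c2", "clonality"] == "LC"

    def test_malformed_chain_rows_rejected(self, caplog):
        rows = paired_cell("c1") + [contig("c2", "IGH", "V", "J", "TGT")]
        table = call_clonotypes(make_contigs(rows), "P1")
        cells = table.cells.set_index("barcode")
        assert cells.loc["c2", "clonality"] == "none"

    def test_invariant_under_row_shuffles(self, sc_patient):
        contigs = sc_patient["contigs"]
        barcodes = sc_patient["norm"].barcodes
        a = call_clonotypes(contigs, "P1", barcodes=barcodes)
        shuffled = contigs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        b = call_clonotypes(shuffled, "P1", barcodes=barcodes)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_recovers_generator_clone_sizes(self, sc_patient):
        table = call_clonotypes(sc_patient["contigs"], "P1",
                                barcodes=sc_patient["norm"].barcodes)
        truth = sc_patient["truth_cells"]
        called = table.cells.set_index("barcode").reindex(truth.index)
        with_ct = called["clonotype_id"].notna()
        assert with_ct.equals(truth["clonotype_id"].notna())
        # QC removed some clone members, so compare against planted clone
        # sizes recounted among the surviving cells
        surviving = truth.loc[with_ct, "clonotype_id"].value_counts()
        expected = truth.loc[with_ct, "clonotype_id"].map(surviving)
        assert (called.loc[with_ct, "clone_size"] == expected).all()

    def test_size_class_boundaries(self):
        assert [size_class(n) for n in (1, 2, 3, 10, 11, 100, 101)] == [
            "1", "2", "3-10", "3-10", "11-100", "11-100", ">100",
        ]


class TestRepertoireMetrics:
    def _toy_table(self):
        # 7 cells in clones of sizes {1, 1, 2, 3}: expanded cells = 3/7
        rows = []
        for i, (cid, size) in enumerate([("a", 1), ("b", 1), ("c", 2), ("c", 2),
                                         ("d", 3), ("d", 3), ("d", 3)]):
            rows.append({"barcode": f"c{i}", "clonotype_id": f"P1_{cid}",
                         "n_productive_chains": 2, "clone_size": size,
                         "clonality": "HC" if size >= 3 else "LC",
                         "size_class": size_class(size)})
        from ticp.tcr import ClonotypeTable
        return ClonotypeTable(patient="P1", cells=pd.DataFrame(rows))

    def test_counting_by_definition(self):
        table = self._toy_table()
        clusters = pd.Series(["K"] * 7, index=[f"c{i}" for i in range(7)])
        out = repertoire_metrics([table], {"P1": clusters}, {"K": "CD4"})
        row = out["per_cluster"].iloc[0]
        assert row["n_clonotypes"] == 4
        assert row["pct_productive"] == 100.0
        assert row["clonotypes_1"] == 2 and row["clonotypes_2"] == 1
        lin = out["per_lineage"].iloc[0]
        assert lin["pct_expanded"] == pytest.approx(100 * 3 / 7)

    def test_all_singletons(self):
        rows = [{"barcode": f"c{i}", "clonotype_id": f"P1_x{i}",
                 "n_productive_chains": 2, "clone_size": 1, "clonality": "LC",
                 "size_class": "1"} for i in range(5)]
        from ticp.tcr import ClonotypeTable
        table = ClonotypeTable(patient="P1", cells=pd.DataFrame(rows))
        clusters = pd.Series(["K"] * 5, index=[f"c{i}" for i in range(5)])
        out = repertoire_metrics([table], {"P1": clusters}, {"K": "CD8"})
        assert out["per_cluster"].iloc[0]["n_clonotypes"] == 5
        assert out["per_lineage"].iloc[0]["pct_expanded"] == 0.0

    def test_size_class_counts_sum_to_unique_clonotypes(self, sc_patient):
        table = call_clonotypes(sc_patient["contigs"], "P1",
                                barcodes=sc_patient["norm"].barcodes)
        clusters = sc_patient["truth_cells"]["cluster"]
        out = repertoire_metrics([table], {"P1": clusters})
        per = out["per_cluster"]
        class_sum = per[[f"clonotypes_{c}" for c in SIZE_CLASSES]].sum(axis=1)
        assert (class_sum == per["n_clonotypes"]).all()


class TestSharing:
    def _table(self, assignment):
        rows = []
        for i, cid in enumerate(assignment):
            size = assignment.count(cid)
            rows.append({"barcode": f"c{i}", "clonotype_id": f"P1_{cid}",
                         "n_productive_chains": 2, "clone_size": size,
                         "clonality": "HC" if size >= 3 else "LC",
                         "size_class": size_class(size)})
        from ticp.tcr import ClonotypeTable
        return ClonotypeTable(patient="P1", cells=pd.DataFrame(rows))

    def test_confined_clonotypes_share_nothing(self):
        table = self._table(list("aabbcc"))
        clusters = pd.Series(["K1"] * 2 + ["K2"] * 2 + ["K1"] * 2,
                             index=[f"c{i}" for i in range(6)])
        summary, flows = clonotype_sharing([table], {"P1": clusters})
        assert summary.set_index("patient").loc["P1", "pct_shared"] == 0.0
        assert len(flows) == 0

    def test_one_in_ten_spanning_gives_ten_percent(self):
        # clonotype "a" has cells in two clusters; nine singleton clonotypes
        assignment = ["a", "a"] + [chr(98 + i) for i in range(9)]
        table = self._table(assignment)
        clusters = pd.Series(["K1"] + ["K2"] * 10,
                             index=[f"c{i}" for i in range(11)])
        summary, flows = clonotype_sharing([table], {"P1": clusters})
        assert summary.set_index("patient").loc["P1", "pct_shared"] == 10.0
        assert len(flows) == 1
        assert flows.iloc[0]["cluster_a"] == "K1"

    def test_clonotype_ids_never_cross_patients(self):
        cohort = generate_sc_cohort(
            ScSimConfig(n_patients=3, cells_per_patient=500, seed=9)
        )
        id_sets = []
        for cm, contigs, _ in cohort:
            table = call_clonotypes(contigs, cm.patient, barcodes=cm.barcodes)
            id_sets.append(set(table.cells["clonotype_id"].dropna()))
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (id_sets[i] & id_sets[j])
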