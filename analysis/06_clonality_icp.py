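"""Clonality × checkpoint-expression stratification (the HC/LC × HE/LE map).

Joins each patient's normalized expression, clonotype calls and inferred
clusters; computes per-patient checkpoint medians, the HE/LE class, the
four compartments and their per-cluster composition, the per-cell
checkpoint burden with HC-vs-LC tests, and the LC→HC fold-change map.
Writes results/clonex/ and prints the headline association: the share of
HC_HE CD4 cells that sit in the regulatory cluster.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ticp.clonality import (ICPPanel, PatientCells, classify_expression,
                            compartmentalize, icp_burden, icp_medians,
                            lc_hc_differential)
from ticp.io import read_contigs, read_count_matrix
from ticp.sc import lognormalize, qc_filter
from ticp.tcr import call_clonotypes

IN_COHORT = Path("results/cohort/sc")
IN_SC = Path("results/sc")
OUT = Path("results/clonex")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    panel = ICPPanel()
    patients, treg_clusters, cd4_clusters = [], set(), set()
    for pdir in sorted(IN_COHORT.iterdir()):
        patient = pdir.name
        cm = read_count_matrix(pdir, patient)
        filtered, _ = qc_filter(cm)
        norm = lognormalize(filtered)
        contigs = read_contigs(pdir / "filtered_contig_annotations.csv")
        table = call_clonotypes(contigs, patient, barcodes=norm.barcodes)
        ann = pd.read_csv(IN_SC / patient / "clusters.tsv", sep="\t")
        ann = ann.set_index("barcode").reindex(norm.barcodes)
        # cluster labels are per-patient; prefix them for cohort-level maps
        labels = pd.Series([f"{patient}.{c}" for c in ann["cluster"]],
                           index=norm.barcodes)
        for c, lin in zip(ann["cluster"], ann["lineage"]):
            if lin == "Treg":
                treg_clusters.add(f"{patient}.{c}")
            elif lin == "CD4":
                cd4_clusters.add(f"{patient}.{c}")
        patients.append(PatientCells(norm=norm, clonotypes=table,
                                     clusters=labels))

    medians = icp_medians(patients, panel)
    expression = classify_expression(patients, medians, panel)
    cells, composition = compartmentalize(patients, expression)
    burden_cells, burden_summary = icp_burden(patients, panel)
    diff = lc_hc_differential(patients, panel)

    medians.to_csv(OUT / "icp_medians.tsv", sep="\t")
    cells.to_csv(OUT / "compartments.tsv", sep="\t", index=False)
    composition.to_csv(OUT / "compartment_composition.tsv", sep="\t")
    burden_summary.to_csv(OUT / "icp_burden.tsv", sep="\t", index=False)
    diff.to_csv(OUT / "lc_hc_differential.tsv", sep="\t")

    cd4_side = cells[cells["cluster"].isin(treg_clusters | cd4_clusters)]
    hc_he = cd4_side[cd4_side["compartment"] == "HC_HE"]
    share = 100.0 * hc_he["cluster"].isin(treg_clusters).mean()
    print(f"HC_HE CD4 cells: {len(hc_he)}; "
          f"{share:.1f}% belong to the FoxP3+/regulatory cluster")
    treg_rows = burden_summary[burden_summary["cluster"].isin(treg_clusters)]
    print("regulatory-cluster checkpoint burden (HC vs LC):")
    print(treg_rows[["cluster", "hc_mean", "lc_mean", "p_adj"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
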