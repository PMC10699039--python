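"""Generate the synthetic study cohorts and write them in standard formats.

Emits a 10-sample flow-cytometry cohort (CSV per sample, 10,000 cells,
15 markers) and a 5-patient scRNA-seq cohort (10x-layout MTX trio plus
filtered_contig_annotations.csv per patient, 5,000 cells) under
results/cohort/, together with the generator ground truth. Downstream
scripts re-derive everything from these files.
"""

from pathlib import Path

from ticp.io import (write_contigs, write_count_matrix, write_flow_csv,
                     write_flow_truth, write_sc_truth)
from ticp.simulate import (FlowSimConfig, ScSimConfig, generate_flow_cohort,
                           generate_sc_cohort)

SEED = 20230
OUT = Path("results/cohort")


def main():
    flow_cfg = FlowSimConfig(n_samples=10, cells_per_sample=10_000, seed=SEED)
    flow = generate_flow_cohort(flow_cfg)
    for m, truth in flow:
        write_flow_csv(m, OUT / "flow" / f"{m.sample_id}.csv")
        write_flow_truth(truth, OUT / "flow" / f"{m.sample_id}_truth.json")
    print(f"flow cohort: {len(flow)} samples × {flow_cfg.cells_per_sample} cells")

    sc_cfg = ScSimConfig(n_patients=5, cells_per_patient=5_000, seed=SEED + 1)
    cohort = generate_sc_cohort(sc_cfg)
    for cm, contigs, truth in cohort:
        d = OUT / "sc" / cm.patient
        write_count_matrix(cm, d)
        write_contigs(contigs, d / "filtered_contig_annotations.csv")
        write_sc_truth(truth, d / "truth.json")
        n_ct = truth.cells["clonotype_id"].notna().sum()
        print(f"{cm.patient}: {cm.shape[0]} cells × {cm.shape[1]} genes, "
              f"{n_ct} cells with productive TCR")


if __name__ == "__main__":
    main()
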