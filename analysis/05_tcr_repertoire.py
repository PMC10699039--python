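"""TCR repertoire: clonotype calling, diversity, expansion, sharing.

Merges each patient's contig annotations with the clustered expression
barcodes from 04, assigns patient-scoped clonotypes (strict chain key),
and writes per-cluster diversity/size-class tables, per-lineage expansion
rates, and the cross-cluster sharing summary + Sankey flow table to
results/tcr/.
"""

from pathlib import Path

import pandas as pd

from ticp.io import read_contigs
from ticp.tcr import call_clonotypes, clonotype_sharing, repertoire_metrics

IN_COHORT = Path("results/cohort/sc")
IN_SC = Path("results/sc")
OUT = Path("results/tcr")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    tables, cluster_map, lineage_map = [], {}, {}
    for pdir in sorted(IN_COHORT.iterdir()):
        patient = pdir.name
        contigs = read_contigs(pdir / "filtered_contig_annotations.csv")
        clusters = pd.read_csv(IN_SC / patient / "clusters.tsv", sep="\t")
        table = call_clonotypes(contigs, patient,
                                barcodes=clusters["barcode"].tolist())
        tables.append(table)
        cluster_map[patient] = pd.Series(
            clusters["cluster"].to_numpy(), index=clusters["barcode"])
        lineage_map.update(dict(zip(clusters["cluster"], clusters["lineage"])))
        table.cells.to_csv(OUT / f"{patient}_clonotypes.tsv", sep="\t",
                           index=False)

    metrics = repertoire_metrics(tables, cluster_map, lineage_map)
    metrics["per_cluster"].to_csv(OUT / "repertoire_per_cluster.tsv", sep="\t",
                                  index=False)
    metrics["per_lineage"].to_csv(OUT / "repertoire_per_lineage.tsv", sep="\t",
                                  index=False)
    summary, flows = clonotype_sharing(tables, cluster_map)
    summary.to_csv(OUT / "sharing_summary.tsv", sep="\t", index=False)
    flows.to_csv(OUT / "sharing_flows.tsv", sep="\t", index=False)

    print(metrics["per_lineage"].round(1).to_string(index=False))
    pooled = summary.set_index("patient").loc["pooled"]
    print(f"clonotype sharing: {pooled['pct_shared']:.1f}% of "
          f"{int(pooled['n_clonotypes'])} clonotypes span ≥2 clusters")


if __name__ == "__main__":
    main()
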