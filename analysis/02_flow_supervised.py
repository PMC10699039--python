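"""Supervised flow analysis: subsets, checkpoint positivity/MFI, co-positivity.

Reads the flow cohort written by 01, gates each sample hierarchically,
and writes per-sample subset fractions, per-subset checkpoint profiles,
the Treg/Tconv MFI-ratio vector, the CD25×CD39 co-positivity summary and
Kruskal–Wallis + Dunn comparisons of positivity across subsets to
results/flow/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ticp.flow import (assign_subsets, co_positivity, group_compare,
                       icp_profile, mfi_ratio_heatmap, subset_fractions)
from ticp.io import read_flow_csv
from ticp.simulate import FlowSimConfig, true_thresholds

SEED = 20230
IN = Path("results/cohort/flow")
OUT = Path("results/flow")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    thresholds = true_thresholds(FlowSimConfig(seed=SEED))

    frac_rows, prof_rows, profiles, copos_rows = [], [], [], []
    for path in sorted(IN.glob("S*.csv")):
        m = read_flow_csv(path, path.stem)
        labels = assign_subsets(m, thresholds)
        frac_rows.append({"sample": m.sample_id,
                          **subset_fractions(labels).to_dict()})
        for prof in icp_profile(m, labels, thresholds):
            profiles.append(prof)
            for icp in m.panel:
                prof_rows.append({
                    "sample": m.sample_id, "subset": prof.subset, "icp": icp,
                    "percent_positive": prof.percent_positive[icp],
                    "mfi": prof.mfi[icp]})
        res = co_positivity(m, labels, "CD25", "CD39", thresholds)
        copos_rows.append({"sample": m.sample_id,
                           "treg_double_pos_pct":
                               res.double_positive_pct["CD4FoxP3pos"],
                           "foxp3_share_of_cd4_dp":
                               res.foxp3_share_of_cd4_double_pos})

    fractions = pd.DataFrame(frac_rows)
    prof_df = pd.DataFrame(prof_rows)
    fractions.to_csv(OUT / "subset_fractions.tsv", sep="\t", index=False)
    prof_df.to_csv(OUT / "icp_profiles.tsv", sep="\t", index=False)
    mfi_ratio_heatmap(profiles).rename_axis("icp").reset_index().to_csv(
        OUT / "mfi_ratio_treg_over_tconv.tsv", sep="\t", index=False)
    pd.DataFrame(copos_rows).to_csv(OUT / "cd25_cd39_copositivity.tsv",
                                    sep="\t", index=False)

    # positivity differs across subsets? one omnibus+Dunn test per checkpoint
    test_rows = []
    for icp, grp in prof_df.groupby("icp"):
        groups = {s: g["percent_positive"].to_numpy()
                  for s, g in grp.groupby("subset")}
        rep = group_compare(groups)
        row = {"icp": icp, "H": rep.statistic, "p": rep.p_value}
        if rep.dunn:
            for (a, b), padj in zip(rep.dunn.pairs, rep.dunn.p_adj):
                row[f"p_adj[{a}|{b}]"] = padj
        test_rows.append(row)
    pd.DataFrame(test_rows).to_csv(OUT / "subset_positivity_tests.tsv",
                                   sep="\t", index=False)

    med = fractions[["CD8", "CD4FoxP3neg", "CD4FoxP3pos"]].median()
    print("median %% of T-cells:", med.round(1).to_dict())
    treg_cd39 = prof_df.query("subset=='CD4FoxP3pos' and icp=='CD39'")
    print("Treg CD39+ %:", round(treg_cd39["percent_positive"].mean(), 1))
    print("Treg/Tconv MFI ratio extremes:",
          mfi_ratio_heatmap(profiles).sort_values().iloc[[0, -1]].round(2).to_dict())


if __name__ == "__main__":
    main()
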