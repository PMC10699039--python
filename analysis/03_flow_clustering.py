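"""Unsupervised flow clustering (logicle → kNN-Jaccard → Louvain) + UMAP.

Pools a subsample of the cohort's cells, transforms the 12 clustering
channels (10 checkpoints + CD4 + CD8) with the auto-logicle, builds the
k = 30 Jaccard graph, finds Louvain communities, and writes labels,
normalized per-cluster marker profiles, per-sample abundances, and the
2-D UMAP embedding to results/cluster/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ticp.config import DEFAULT_CLUSTER_MARKERS
from ticp.io import read_flow_csv
from ticp.logicle import auto_logicle_params, logicle_transform
from ticp.phenograph import (knn_jaccard_graph, louvain_cluster,
                             summarize_clusters, umap_embed)

SEED = 20230
IN = Path("results/cohort/flow")
OUT = Path("results/cluster")
MAX_CELLS = 6000


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    frames, samples = [], []
    for path in sorted(IN.glob("S*.csv")):
        m = read_flow_csv(path, path.stem)
        frames.append(m.values)
        samples.extend([m.sample_id] * len(m.values))
    pooled = pd.concat(frames, ignore_index=True)
    samples = np.array(samples)

    rng = np.random.default_rng(SEED)
    if len(pooled) > MAX_CELLS:
        keep = np.sort(rng.choice(len(pooled), MAX_CELLS, replace=False))
        pooled, samples = pooled.iloc[keep].reset_index(drop=True), samples[keep]

    transformed = pd.DataFrame({
        mk: logicle_transform(pooled[mk].to_numpy(),
                              auto_logicle_params(pooled[mk].to_numpy()))
        for mk in DEFAULT_CLUSTER_MARKERS})

    graph = knn_jaccard_graph(transformed.to_numpy(), k=30)
    labels, q = louvain_cluster(graph, seed=SEED)
    print(f"{len(np.unique(labels))} communities, modularity Q = {q:.3f}")

    pd.DataFrame({"cell": np.arange(len(labels)), "sample": samples,
                  "cluster": labels}).to_csv(OUT / "labels.tsv", sep="\t",
                                             index=False)
    rows = []
    for s in summarize_clusters(transformed, labels, samples):
        for mk, v in s.normalized_mean.items():
            rows.append({"cluster": s.cluster, "kind": "marker", "name": mk,
                         "value": v})
        for sid, v in s.abundance.items():
            rows.append({"cluster": s.cluster, "kind": "abundance",
                         "name": sid, "value": v})
    pd.DataFrame(rows).to_csv(OUT / "cluster_summary.tsv", sep="\t", index=False)

    emb = umap_embed(transformed.to_numpy(), n_neighbors=30, min_dist=0.1,
                     seed=SEED)
    pd.DataFrame({"umap1": emb[:, 0], "umap2": emb[:, 1], "cluster": labels,
                  "sample": samples}).to_csv(OUT / "embedding.tsv", sep="\t",
                                             index=False)


if __name__ == "__main__":
    main()
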