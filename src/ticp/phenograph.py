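"""PhenoGraph-style unsupervised clustering of cytometry data.

The recipe: logicle-transform marker intensities, build a k-nearest-
neighbour graph (Euclidean, k = 30 by default), re-weight edges by the
Jaccard overlap of the two endpoints' neighbour sets, and find communities
by Louvain modularity optimisation. The Louvain implementation here is
deliberately self-contained so that the only randomness is the seeded node
visiting order, which makes partitions reproducible and (up to relabeling)
equivariant under permutations of the input cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "WeightedGraph",
    "ClusterSummary",
    "knn_indices",
    "knn_jaccard_graph",
    "louvain_cluster",
    "modularity",
    "summarize_clusters",
    "umap_embed",
]


@dataclass
class WeightedGraph:
    """Undirected weighted graph as a symmetric edge list (i < j)."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int
    weights: np.ndarray  # (m,) float in (0, 1] for Jaccard graphs

    def __post_init__(self):
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights must have equal length")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")

    def adjacency(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        a = sparse.coo_matrix(
            (np.concatenate([self.weights, self.weights]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return a.tocsr()


@dataclass
class ClusterSummary:
    cluster: int
    normalized_mean: dict[str, float] = field(default_factory=dict)  # per marker, [0,1]
    abundance: dict[str, float] = field(default_factory=dict)  # per sample, % of cells


def knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours per row (self excluded), ties broken by index."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=min(k + 2, n)).fit(x)
    dist, idx = nn.kneighbors(x)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        d, j = dist[i], idx[i]
        keep = j != i
        d, j = d[keep], j[keep]
        order = np.lexsort((j, d))  # stable: distance then index
        out[i] = j[order][:k]
    return out


def knn_jaccard_graph(x: np.ndarray, k: int = 30) -> WeightedGraph:
    """kNN graph with Jaccard edge weights.

    An edge (i, j) exists iff j is among i's k nearest neighbours or vice
    versa; its weight is the Jaccard overlap of the two *self-inclusive*
    neighbourhoods N(i) = {i} ∪ kNN(i) (duplicated points with identical
    neighbour sets thus get weight exactly 1). Zero-weight edges are
    dropped.
    """
    nbrs = knn_indices(x, k)
    n = len(nbrs)
    rows = np.repeat(np.arange(n), k)
    a = sparse.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, nbrs.ravel())), shape=(n, n)
    )
    candidates = ((a + a.T) > 0).tocoo()
    a = (a + sparse.eye(n, format="csr", dtype=np.int32)).tocsr()  # add self
    mask = candidates.row < candidates.col
    ci, cj = candidates.row[mask], candidates.col[mask]
    inter = np.asarray(a[ci].multiply(a[cj]).sum(axis=1)).ravel()
    union = 2 * (k + 1) - inter
    w = inter / union
    keep = w > 0
    edges = np.column_stack([ci[keep], cj[keep]]).astype(np.int64)
    return WeightedGraph(n_nodes=n, edges=edges, weights=w[keep])


def modularity(g: WeightedGraph, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Weighted Newman modularity Q of a partition (no self-loops)."""
    labels = np.asarray(labels)
    w = g.weights
    two_m = 2.0 * w.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    deg = np.zeros(g.n_nodes)
    np.add.at(deg, g.edges[:, 0], w)
    np.add.at(deg, g.edges[:, 1], w)
    same = labels[g.edges[:, 0]] == labels[g.edges[:, 1]]
    intra = w[same].sum()
    q = 2.0 * intra / two_m
    for c in np.unique(labels):
        dc = deg[labels == c].sum()
        q -= resolution * (dc / two_m) ** 2
    return float(q)


def _one_level(
    neighbors: list[dict[int, float]],
    self_loops: np.ndarray,
    degrees: np.ndarray,
    two_m: float,
    order: np.ndarray,
    resolution: float,
    max_passes: int = 100,
) -> np.ndarray:
    """Louvain local-moving phase; returns node → community."""
    n = len(neighbors)
    com = np.arange(n)
    tot = degrees.copy()  # sum of degrees per community
    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for node in order:
            c_old = com[node]
            ki = degrees[node]
            # weights from node to each neighbouring community
            links: dict[int, float] = {}
            for nb, w in neighbors[node].items():
                links[com[nb]] = links.get(com[nb], 0.0) + w
            tot[c_old] -= ki
            base = links.get(c_old, 0.0) - resolution * ki * tot[c_old] / two_m
            best_c, best_gain = c_old, base
            for c, w_in in links.items():
                if c == c_old:
                    continue
                gain = w_in - resolution * ki * tot[c] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            tot[best_c] += ki
            if best_c != c_old:
                com[node] = best_c
                improved = True
    return com


def _aggregate(
    neighbors: list[dict[int, float]],
    self_loops: np.ndarray,
    com: np.ndarray,
) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes."""
    cs = np.unique(com)
    remap = {c: i for i, c in enumerate(cs)}
    k = len(cs)
    new_nb: list[dict[int, float]] = [dict() for _ in range(k)]
    new_loops = np.zeros(k)
    for node, nbrs in enumerate(neighbors):
        a = remap[com[node]]
        new_loops[a] += self_loops[node]
        for nb, w in nbrs.items():
            if nb <= node:
                continue
            b = remap[com[nb]]
            if a == b:
                new_loops[a] += w
            else:
                new_nb[a][b] = new_nb[a].get(b, 0.0) + w
                new_nb[b][a] = new_nb[b].get(a, 0.0) + w
    new_com = np.array([remap[c] for c in com])
    return new_nb, new_loops, new_com


def louvain_cluster(
    g: WeightedGraph,
    seed: int = 0,
    resolution: float = 1.0,
    order: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Louvain community detection; returns (labels, modularity Q).

    Deterministic given ``seed``: the only stochastic element is the node
    visiting order of the first level, drawn from the seeded generator (an
    explicit ``order`` overrides it). Labels are renumbered 0..K−1 by first
    appearance.
    """
    if len(g.edges) == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)

    neighbors: list[dict[int, float]] = [dict() for _ in range(g.n_nodes)]
    for (i, j), w in zip(g.edges, g.weights):
        neighbors[i][j] = neighbors[i].get(j, 0.0) + w
        neighbors[j][i] = neighbors[j].get(i, 0.0) + w
    self_loops = np.zeros(g.n_nodes)
    two_m = 2.0 * g.weights.sum()

    membership = np.arange(g.n_nodes)
    first = True
    while True:
        n = len(neighbors)
        degrees = np.array(
            [sum(nb.values()) + 2.0 * self_loops[i] for i, nb in enumerate(neighbors)]
        )
        if first and order is not None:
            visit = np.asarray(order)
        else:
            visit = rng.permutation(n)
        first = False
        com = _one_level(neighbors, self_loops, degrees, two_m, visit, resolution)
        if np.all(com == np.arange(n)) or len(np.unique(com)) == n:
            break
        neighbors, self_loops, new_com = _aggregate(neighbors, self_loops, com)
        membership = new_com[membership]
        if len(neighbors) == 1:
            break

    # renumber by first appearance for determinism
    labels = np.asarray(membership)
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, c in enumerate(labels):
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out, modularity(g, out)


def summarize_clusters(
    values: pd.DataFrame,
    labels: np.ndarray,
    sample_ids: np.ndarray | pd.Series,
) -> list[ClusterSummary]:
    """Per-cluster marker profile and per-sample abundance.

    Marker means are min-max normalized per marker across clusters (a
    degenerate marker with min == max maps to 0); abundances are percent of
    each sample's cells and sum to 100 per sample.
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if len(labels) != len(values):
        raise ValueError("labels must cover all cells")
    clusters = np.unique(labels)

    means = pd.DataFrame(
        {c: values.loc[labels == c].mean(axis=0) for c in clusters}
    ).T  # clusters × markers
    rng_span = means.max(axis=0) - means.min(axis=0)
    norm = (means - means.min(axis=0)).div(rng_span.replace(0, np.nan)).fillna(0.0)

    out = []
    samples = np.unique(sample_ids)
    for c in clusters:
        summ = ClusterSummary(cluster=int(c), normalized_mean=norm.loc[c].to_dict())
        for s in samples:
            in_s = sample_ids == s
            summ.abundance[str(s)] = float(
                100.0 * np.mean(labels[in_s] == c)
            ) if in_s.sum() else 0.0
        out.append(summ)
    return out


def umap_embed(
    x: np.ndarray, n_neighbors: int = 30, min_dist: float = 0.1, seed: int = 0
) -> np.ndarray:
    """2-D UMAP embedding with the study's parameters (thin wrapper)."""
    import umap

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed, n_components=2
    )
    return reducer.fit_transform(np.asarray(x, dtype=float))
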