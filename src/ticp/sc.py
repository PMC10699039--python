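"""scRNA-seq stage: QC, normalization, HVG selection, clustering grids,
cell-cycle scoring, lineage assignment, and filtered differential expression.

The processing mirrors the standard droplet scRNA-seq workflow for T-cell
atlases: hard QC cutoffs (gene detected in ≥5 cells; cell with ≥1000 UMIs,
≥200 genes, ≤20% mitochondrial reads), library-size log-normalization,
variance-stabilized selection of 3000 highly variable genes, a grid of
reduced dimensionalities (3–49, step 2) × clustering resolutions (0.1–1.2,
step 0.1) with a stability report, and Wilcoxon rank-sum differential
expression filtered at |log2FC| ≥ 0.58 (fold change 1.5), ≥25% expressing
cells in one group, and BH-adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .phenograph import knn_jaccard_graph
from .simulate import CountMatrix
from .stats import bh_adjust, mann_whitney

log = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "NormMatrix",
    "ClusterGridResult",
    "qc_filter",
    "lognormalize",
    "select_hvg",
    "reduce_and_cluster",
    "score_cell_cycle",
    "default_cell_cycle_genes",
    "default_lineage_sets",
    "assign_lineage",
    "differential_expression",
]


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_cells_per_gene: int = Field(default=5, gt=0)
    min_umi: int = Field(default=1000, gt=0)
    min_genes: int = Field(default=200, gt=0)
    max_mito_frac: float = Field(default=0.20, gt=0, le=1)
    mito_prefix: str = "MT-"


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    genes_removed_low_cells: int
    cells_removed_low_umi: int
    cells_removed_low_genes: int
    cells_removed_high_mito: int
    n_cells_out: int
    n_genes_out: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NormMatrix:
    """Log-normalized expression, cells × genes; raw counts kept alongside
    for detection-based statistics (pct expressing, checkpoint burden)."""

    patient: str
    values: sparse.csr_matrix  # ln(1 + count * scale / cell_total)
    counts: sparse.csr_matrix
    barcodes: list[str]
    genes: list[str]

    def gene_index(self, symbols: list[str]) -> list[int]:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return [lookup[s] for s in symbols if s in lookup]

    def column(self, symbol: str) -> np.ndarray:
        return np.asarray(
            self.values[:, self.genes.index(symbol)].todense()
        ).ravel()


def qc_filter(c: CountMatrix, q: QCConfig | None = None) -> tuple[CountMatrix, QCReport]:
    """Apply the four QC cutoffs; gene filter first (on the input cells),
    then the three cell filters on the gene-filtered matrix."""
    q = q or QCConfig()
    if c.counts.shape[0] == 0 or c.counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    x = c.counts.tocsc()

    cells_per_gene = np.asarray((x > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= q.min_cells_per_gene
    x = x[:, gene_keep].tocsr()
    genes = [g for g, k in zip(c.genes, gene_keep) if k]

    umi = np.asarray(x.sum(axis=1)).ravel()
    n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    mito_cols = [i for i, g in enumerate(genes) if g.startswith(q.mito_prefix)]
    mito = (
        np.asarray(x[:, mito_cols].sum(axis=1)).ravel()
        if mito_cols
        else np.zeros(len(umi))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito / np.maximum(umi, 1), 1.0)

    low_umi = umi < q.min_umi
    low_genes = n_genes < q.min_genes
    high_mito = mito_frac > q.max_mito_frac
    cell_keep = ~(low_umi | low_genes | high_mito)

    report = QCReport(
        n_cells_in=c.counts.shape[0],
        n_genes_in=c.counts.shape[1],
        genes_removed_low_cells=int((~gene_keep).sum()),
        cells_removed_low_umi=int(low_umi.sum()),
        cells_removed_low_genes=int(low_genes.sum()),
        cells_removed_high_mito=int(high_mito.sum()),
        n_cells_out=int(cell_keep.sum()),
        n_genes_out=len(genes),
    )
    if report.n_cells_out == 0 or report.n_genes_out == 0:
        raise ValueError(f"QC removed everything: {report.as_dict()}")
    out = CountMatrix(
        patient=c.patient,
        counts=x[cell_keep].tocsr(),
        barcodes=[b for b, k in zip(c.barcodes, cell_keep) if k],
        genes=genes,
    )
    return out, report


def lognormalize(c: CountMatrix, scale: float = 10_000.0) -> NormMatrix:
    """value = ln(1 + count · scale / cell_total)."""
    totals = np.asarray(c.counts.sum(axis=1)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts; run QC first")
    x = c.counts.tocsr().astype(float)
    scaler = sparse.diags(scale / totals)
    x = scaler @ x
    x.data = np.log1p(x.data)
    return NormMatrix(
        patient=c.patient,
        values=x.tocsr(),
        counts=c.counts.tocsr(),
        barcodes=list(c.barcodes),
        genes=list(c.genes),
    )


def select_hvg(c: CountMatrix, n: int = 3000, loess_frac: float = 0.3) -> list[str]:
    """Variance-stabilizing HVG selection on raw counts.

    Per gene, the expected standard deviation is read off a local-regression
    (lowess) fit of log10(variance) against log10(mean); standardized values
    are clipped at sqrt(n_cells) and their variance ranks the genes.
    Ties break by gene order. Requesting more genes than exist returns all
    genes with a warning.
    """
    n_cells, n_genes = c.counts.shape
    if n_cells < 2:
        raise ValueError("need at least two cells")
    if n > n_genes:
        log.warning("requested %d HVGs but only %d genes; returning all", n, n_genes)
        return list(c.genes)

    x = c.counts.tocsc().astype(float)
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_cells / (n_cells - 1)

    std_var = np.zeros(n_genes)
    ok = var > 0
    if ok.sum() == 0:
        raise ValueError("all genes have zero variance")
    fit = lowess(
        np.log10(var[ok]), np.log10(mean[ok]), frac=loess_frac, return_sorted=False
    )
    sd_exp = np.sqrt(10.0**fit)
    clip = np.sqrt(n_cells)

    ok_idx = np.flatnonzero(ok)
    for pos, g in enumerate(ok_idx):
        sd = sd_exp[pos]
        nz = x.data[x.indptr[g] : x.indptr[g + 1]]
        z_nz = np.minimum((nz - mean[g]) / sd, clip)
        z0 = min((0.0 - mean[g]) / sd, clip)
        sumsq = (n_cells - len(nz)) * z0**2 + np.sum(z_nz**2)
        mu_z = ((n_cells - len(nz)) * z0 + z_nz.sum()) / n_cells
        std_var[g] = (sumsq - n_cells * mu_z**2) / (n_cells - 1)

    order = np.argsort(-std_var, kind="stable")
    return [c.genes[i] for i in order[:n]]


# --------------------------------------------------------------------------
# dimensionality / resolution grid
# --------------------------------------------------------------------------

DIMS_GRID_DEFAULT = tuple(range(3, 50, 2))  # 24 candidate dimensionalities
RES_GRID_DEFAULT = tuple(round(0.1 * i, 1) for i in range(1, 13))  # 0.1 .. 1.2


@dataclass
class ClusterGridResult:
    dims: int
    resolution: float
    labels: np.ndarray
    embedding: np.ndarray  # cells × chosen dims
    report: pd.DataFrame  # one row per (dims, resolution)


def _leiden_partition(graph, resolution: float, seed: int) -> np.ndarray:
    """Modularity optimization with a resolution parameter (Leiden/RB)."""
    import igraph as ig
    import leidenalg

    g = ig.Graph(
        n=graph.n_nodes,
        edges=[(int(i), int(j)) for i, j in graph.edges],
        edge_attrs={"weight": list(map(float, graph.weights))},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.array(part.membership)


def reduce_and_cluster(
    norm: NormMatrix,
    hvg: list[str],
    dims_grid: tuple[int, ...] = DIMS_GRID_DEFAULT,
    res_grid: tuple[float, ...] = RES_GRID_DEFAULT,
    seed: int = 0,
    knn_k: int = 20,
    stability_floor: float = 0.5,
    silhouette_max_cells: int = 2000,
) -> ClusterGridResult:
    """Cluster over a (dimensions × resolution) grid and pick a stable optimum.

    The embedding is a centered truncated SVD (PCA) of the HVG expression;
    each dimensionality gets a kNN-Jaccard graph and modularity-optimized
    partitions across the resolution grid. Stability of a grid point is the
    mean adjusted Rand index against the partitions at neighbouring
    resolutions; the chosen point maximizes mean silhouette width subject
    to stability ≥ ``stability_floor``.
    """
    idx = norm.gene_index(hvg)
    x = np.asarray(norm.values[:, idx].todense(), dtype=float)
    n_cells = x.shape[0]
    max_dims = min(n_cells, len(idx)) - 1
    dims = [d for d in dims_grid if d <= max_dims]
    if len(dims) < len(dims_grid):
        log.warning("dropped %d dimensionalities exceeding the data rank",
                    len(dims_grid) - len(dims))
    if not dims:
        raise ValueError("no usable dimensionality in the grid")

    x -= x.mean(axis=0)
    pca = PCA(n_components=max(dims), svd_solver="full" if n_cells < 3000 else "randomized",
              random_state=seed)
    pcs = pca.fit_transform(x)

    rng = np.random.default_rng(seed)
    sil_cells = (
        rng.choice(n_cells, size=silhouette_max_cells, replace=False)
        if n_cells > silhouette_max_cells
        else np.arange(n_cells)
    )

    rows = []
    all_labels: dict[tuple[int, float], np.ndarray] = {}
    for d in dims:
        emb = pcs[:, :d]
        graph = knn_jaccard_graph(emb, k=min(knn_k, n_cells - 1))
        for r in res_grid:
            all_labels[(d, r)] = _leiden_partition(graph, r, seed)

    for d in dims:
        emb = pcs[:, :d]
        for ri, r in enumerate(res_grid):
            labels = all_labels[(d, r)]
            n_clusters = len(np.unique(labels))
            neighbours = []
            if ri > 0:
                neighbours.append(adjusted_rand_score(labels, all_labels[(d, res_grid[ri - 1])]))
            if ri < len(res_grid) - 1:
                neighbours.append(adjusted_rand_score(labels, all_labels[(d, res_grid[ri + 1])]))
            stability = float(np.mean(neighbours)) if neighbours else 1.0
            if n_clusters >= 2 and n_clusters < len(sil_cells):
                sil = float(
                    silhouette_score(emb[sil_cells], labels[sil_cells])
                    if len(np.unique(labels[sil_cells])) >= 2
                    else np.nan
                )
            else:
                sil = np.nan
            rows.append(
                {"dims": d, "resolution": r, "n_clusters": n_clusters,
                 "silhouette": sil, "stability": stability}
            )
    report = pd.DataFrame(rows)

    eligible = report.dropna(subset=["silhouette"])
    stable = eligible[eligible["stability"] >= stability_floor]
    if len(stable) == 0:
        log.warning("no grid point met the stability floor %.2f; "
                    "falling back to best silhouette overall", stability_floor)
        stable = eligible
    if len(stable) == 0:
        raise ValueError("no grid point produced a multi-cluster partition")
    best = stable.sort_values(["silhouette", "dims", "resolution"],
                              ascending=[False, True, True]).iloc[0]
    d, r = int(best["dims"]), float(best["resolution"])
    return ClusterGridResult(
        dims=d,
        resolution=r,
        labels=all_labels[(d, r)],
        embedding=pcs[:, :d],
        report=report,
    )


# --------------------------------------------------------------------------
# cell-cycle scoring
# --------------------------------------------------------------------------


def default_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """Bundled S-phase and G2/M gene lists (standard human signatures)."""
    def read(name):
        with resources.files("ticp.data").joinpath(name).open() as fh:
            return [line.strip() for line in fh if line.strip()]
    return read("cc_s_genes.txt"), read("cc_g2m_genes.txt")


def _module_score(
    norm: NormMatrix,
    gene_set: list[str],
    rng: np.random.Generator,
    n_bins: int = 24,
    ctrl_size: int = 100,
) -> np.ndarray:
    """Binned-control module score: mean(set) − mean(matched controls)."""
    present = [g for g in gene_set if g in norm.genes]
    if not present:
        raise ValueError(
            f"none of the score genes are in the matrix: {sorted(gene_set)[:10]}..."
        )
    avg = np.asarray(norm.values.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.arange(len(avg)) * n_bins // len(avg)

    target_idx = np.array(norm.gene_index(present))
    control: set[int] = set()
    for g in target_idx:
        pool = np.flatnonzero(bins == bins[g])
        take = min(ctrl_size, len(pool))
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    control -= set(target_idx.tolist())
    ctrl_idx = np.array(sorted(control))

    set_mean = np.asarray(norm.values[:, target_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(norm.values[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def score_cell_cycle(
    norm: NormMatrix,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M module scores and the called phase.

    Phase is the argmax of (S, G2M) when the maximum is positive, else G1.
    """
    if s_genes is None or g2m_genes is None:
        s_def, g2m_def = default_cell_cycle_genes()
        s_genes = s_genes or s_def
        g2m_genes = g2m_genes or g2m_def
    rng = np.random.default_rng(seed)
    s_score = _module_score(norm, s_genes, rng)
    g2m_score = _module_score(norm, g2m_genes, rng)
    phase = np.where(
        np.maximum(s_score, g2m_score) <= 0,
        "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"S_score": s_score, "G2M_score": g2m_score, "phase": phase},
        index=norm.barcodes,
    )


# --------------------------------------------------------------------------
# lineage assignment
# --------------------------------------------------------------------------


def default_lineage_sets() -> dict[str, list[str]]:
    """Canonical marker sets used to label clusters with a T-cell lineage."""
    return {
        "CD8": ["CD8A", "CD8B"],
        "CD4": ["CD4", "IL7R"],
        "Treg": ["FOXP3", "IL2RA"],
    }


#: accessory programs for descriptive sub-labels (not used for lineage calls)
ACCESSORY_SETS = {
    "cytotoxicity": ["GZMB", "GZMK", "GNLY", "PRF1"],
    "exhaustion": ["PDCD1", "HAVCR2", "LAG3", "TOX"],
}


def assign_lineage(
    labels: np.ndarray,
    norm: NormMatrix,
    sets: dict[str, list[str]] | None = None,
    treg_lineage: str = "Treg",
    foxp3_gene: str = "FOXP3",
    min_foxp3_frac: float = 0.30,
) -> dict[int, str]:
    """Label each cluster with the lineage whose marker set scores highest.

    Scores are cluster means of the set's mean expression, z-scored across
    clusters per lineage. The regulatory label additionally requires FOXP3
    detected in more than ``min_foxp3_frac`` of the cluster's cells;
    otherwise the next-best lineage is used. Ties break by lineage order.
    """
    sets = sets or default_lineage_sets()
    labels = np.asarray(labels)
    if len(labels) != norm.values.shape[0]:
        raise ValueError("cluster labels must cover all cells")
    for lin, genes in sets.items():
        missing = [g for g in genes if g not in norm.genes]
        if missing:
            log.warning("lineage %s: marker genes absent from matrix: %s", lin, missing)

    clusters = np.unique(labels)
    lineages = list(sets)
    scores = np.zeros((len(clusters), len(lineages)))
    for li, lin in enumerate(lineages):
        idx = norm.gene_index(sets[lin])
        if not idx:
            continue
        per_cell = np.asarray(norm.values[:, idx].mean(axis=1)).ravel()
        for ci, c in enumerate(clusters):
            scores[ci, li] = per_cell[labels == c].mean()
    sd = scores.std(axis=0, ddof=0)
    z = (scores - scores.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    foxp3_det = None
    if foxp3_gene in norm.genes:
        col = np.asarray(
            (norm.counts[:, norm.genes.index(foxp3_gene)] > 0).todense()
        ).ravel()
        foxp3_det = col

    out: dict[int, str] = {}
    for ci, c in enumerate(clusters):
        ranked = np.argsort(-z[ci], kind="stable")  # ties by lineage order
        if len(ranked) > 1 and z[ci][ranked[0]] == z[ci][ranked[1]]:
            log.warning("cluster %s: lineage score tie, broken by lineage order", c)
        choice = lineages[ranked[0]]
        if choice == treg_lineage:
            frac = float(foxp3_det[labels == c].mean()) if foxp3_det is not None else 0.0
            if frac <= min_foxp3_frac:
                choice = lineages[ranked[1]] if len(ranked) > 1 else choice
        out[int(c)] = choice
    return out


# --------------------------------------------------------------------------
# differential expression
# --------------------------------------------------------------------------


def differential_expression(
    norm: NormMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_threshold: float = 0.58,
    min_pct: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filtered Wilcoxon rank-sum differential expression between cell groups.

    ``avg_log2FC = log2(mean(expm1(x_A)) + 1) − log2(mean(expm1(x_B)) + 1)``;
    ``pct`` is the fraction of cells with a nonzero count per group. Genes
    are pre-filtered (|avg_log2FC| ≥ 0.58, expressed in ≥25% of one group)
    before testing; BH adjustment runs over the tested genes and only genes
    with adjusted p < 0.05 are reported.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.dtype == bool:
        a = np.flatnonzero(a)
    if b.dtype == bool:
        b = np.flatnonzero(b)
    if len(np.intersect1d(a, b)):
        raise ValueError("groups overlap")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 cells")

    xa = norm.values[a]
    xb = norm.values[b]
    expm1_a = np.asarray(xa.copy().expm1().mean(axis=0)).ravel()
    expm1_b = np.asarray(xb.copy().expm1().mean(axis=0)).ravel()
    log2fc = np.log2(expm1_a + 1.0) - np.log2(expm1_b + 1.0)
    pct_a = np.asarray((norm.counts[a] > 0).mean(axis=0)).ravel()
    pct_b = np.asarray((norm.counts[b] > 0).mean(axis=0)).ravel()

    tested = np.flatnonzero(
        (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2fc) >= lfc_threshold)
    )
    if len(tested) == 0:
        return _empty_de_frame()

    pvals = np.empty(len(tested))
    xa_d = np.asarray(xa[:, tested].todense())
    xb_d = np.asarray(xb[:, tested].todense())
    for k in range(len(tested)):
        pvals[k] = mann_whitney(xa_d[:, k], xb_d[:, k]).p_value
    padj = bh_adjust(pvals)

    df = pd.DataFrame(
        {
            "gene": [norm.genes[i] for i in tested],
            "avg_log2FC": log2fc[tested],
            "pct.1": pct_a[tested],
            "pct.2": pct_b[tested],
            "p_val": pvals,
            "p_val_adj": padj,
        }
    )
    df = df[df["p_val_adj"] < alpha]
    return df.sort_values(["p_val", "gene"], kind="stable").reset_index(drop=True)


def _empty_de_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "avg_log2FC", "pct.1", "pct.2", "p_val", "p_val_adj"]
    )
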