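"""Clonality × checkpoint-expression stratification of T-cells.

Each clonotyped cell gets two labels: HC/LC from its clone size (≥3 cells
vs fewer) and HE/LE from its checkpoint expression relative to per-patient
per-gene medians — a cell is "high expression" when it exceeds the patient
median for at least half of the panel genes. The joint label defines four
compartments (HC_HE, HC_LE, LC_HE, LC_LE) whose per-cluster composition,
together with the per-cell checkpoint burden (number of panel genes
detected) and the LC-vs-HC fold-change map, summarizes how clonal expansion
relates to checkpoint co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from . import ICP_PANEL
from .sc import NormMatrix
from .stats import bh_adjust, mann_whitney
from .tcr import HC_MIN_CLONE, ClonotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "ICPPanel",
    "PatientCells",
    "icp_medians",
    "classify_expression",
    "compartmentalize",
    "icp_burden",
    "lc_hc_differential",
]

COMPARTMENTS = ["HC_HE", "HC_LE", "LC_HE", "LC_LE"]


@dataclass(frozen=True)
class ICPPanel:
    """Ordered checkpoint panel as (protein, gene symbol) pairs."""

    entries: tuple[tuple[str, str], ...] = tuple(ICP_PANEL)

    def __post_init__(self):
        if len(self.entries) < 1:
            raise ValueError("panel must contain at least one checkpoint")
        genes = [g for _, g in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("panel gene symbols must be unique")

    @property
    def genes(self) -> list[str]:
        return [g for _, g in self.entries]

    @property
    def proteins(self) -> list[str]:
        return [p for p, _ in self.entries]

    def present_in(self, norm: NormMatrix) -> list[str]:
        present = [g for g in self.genes if g in norm.genes]
        missing = sorted(set(self.genes) - set(present))
        if missing:
            log.warning("panel genes absent from matrix, dropped: %s", missing)
        return present


@dataclass
class PatientCells:
    """One patient's normalized expression joined with clonotype calls."""

    norm: NormMatrix
    clonotypes: ClonotypeTable
    clusters: pd.Series  # barcode-indexed cluster labels

    def __post_init__(self):
        bc = pd.Index(self.norm.barcodes)
        cells = self.clonotypes.cells.set_index("barcode").reindex(bc)
        self.cells = cells
        self.clusters = self.clusters.reindex(bc)
        self.clonotyped = cells["clonotype_id"].notna().to_numpy()

    @property
    def patient(self) -> str:
        return self.norm.patient


def icp_medians(patients: list[PatientCells], panel: ICPPanel | None = None) -> pd.DataFrame:
    """Per-patient per-checkpoint median normalized expression.

    Medians are taken over all clonotyped T-cells of the patient. Patients
    with no clonotyped cells are omitted.
    """
    panel = panel or ICPPanel()
    rows = {}
    for p in patients:
        genes = panel.present_in(p.norm)
        if p.clonotyped.sum() == 0:
            log.warning("patient %s has no clonotyped cells; omitted", p.patient)
            continue
        sub = p.norm.values[np.flatnonzero(p.clonotyped)][:, p.norm.gene_index(genes)]
        med = np.median(np.asarray(sub.todense()), axis=0)
        rows[p.patient] = dict(zip(genes, med))
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_expression(
    patients: list[PatientCells],
    medians: pd.DataFrame,
    panel: ICPPanel | None = None,
    rule: str = "indicator-majority",
    min_above: int | None = None,
) -> dict[str, pd.Series]:
    """Per-cell HE/LE class relative to the patient's checkpoint medians.

    Default rule: a cell is HE when its expression strictly exceeds the
    patient median for at least ``ceil(panel/2)`` panel genes (5 of 10).
    The alternative rule ``"mean-score"`` calls HE when the cell's mean
    checkpoint expression exceeds the patient median of that mean.
    Only clonotyped cells are labeled (others are NaN).
    """
    panel = panel or ICPPanel()
    out = {}
    for p in patients:
        if p.patient not in medians.index:
            raise ValueError(f"no medians computed for patient {p.patient}")
        genes = [g for g in panel.genes if g in medians.columns and g in p.norm.genes]
        x = np.asarray(p.norm.values[:, p.norm.gene_index(genes)].todense())
        if rule == "indicator-majority":
            need = min_above if min_above is not None else ceil(len(genes) / 2)
            above = x > medians.loc[p.patient, genes].to_numpy()[None, :]
            he = above.sum(axis=1) >= need
        elif rule == "mean-score":
            score = x.mean(axis=1)
            clonotyped_scores = score[p.clonotyped]
            he = score > np.median(clonotyped_scores)
        else:
            raise ValueError(f"unknown expression rule {rule!r}")
        labels = np.where(he, "HE", "LE").astype(object)
        labels[~p.clonotyped] = None
        out[p.patient] = pd.Series(labels, index=p.norm.barcodes, name="expression")
    return out


def compartmentalize(
    patients: list[PatientCells],
    expression: dict[str, pd.Series],
    treg_cluster: str | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint HC/LC × HE/LE compartments and their per-cluster composition.

    Returns (cell table, composition). The cell table has one row per
    clonotyped cell with patient, cluster, clonality, expression and
    compartment. The composition table gives, per cluster, the percent of
    cells in each compartment (summing to 100). When ``treg_cluster`` is
    given, the share of HC_HE CD4-side cells belonging to that cluster is
    attached to the composition frame's ``attrs["hc_he_treg_share_pct"]``.
    """
    frames = []
    for p in patients:
        expr = expression[p.patient].reindex(p.norm.barcodes)
        mask = p.clonotyped
        df = pd.DataFrame(
            {
                "patient": p.patient,
                "barcode": np.array(p.norm.barcodes)[mask],
                "cluster": p.clusters.to_numpy()[mask],
                "clonality": p.cells["clonality"].to_numpy()[mask],
                "expression": expr.to_numpy()[mask],
            }
        )
        frames.append(df)
    cells = pd.concat(frames, ignore_index=True)
    cells["compartment"] = cells["clonality"].astype(str) + "_" + cells["expression"].astype(str)

    comp = (
        cells.groupby(["cluster", "compartment"]).size().unstack(fill_value=0)
        .reindex(columns=COMPARTMENTS, fill_value=0)
    )
    composition = 100.0 * comp.div(comp.sum(axis=1), axis=0)

    if treg_cluster is not None:
        hc_he = cells[cells["compartment"] == "HC_HE"]
        if len(hc_he):
            composition.attrs["hc_he_treg_share_pct"] = float(
                100.0 * (hc_he["cluster"] == treg_cluster).mean()
            )
    return cells, composition


def icp_burden(
    patients: list[PatientCells],
    panel: ICPPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Number of panel checkpoints detected per cell, and HC-vs-LC tests.

    Burden counts panel genes with a nonzero UMI count (0..panel size).
    Returns (per-cell table, per-cluster summary with HC/LC means ± SD and
    a two-sided Mann–Whitney p, BH-adjusted across clusters).
    """
    panel = panel or ICPPanel()
    frames = []
    for p in patients:
        genes = panel.present_in(p.norm)
        det = np.asarray(
            (p.norm.counts[:, p.norm.gene_index(genes)] > 0).sum(axis=1)
        ).ravel()
        frames.append(
            pd.DataFrame(
                {
                    "patient": p.patient,
                    "barcode": p.norm.barcodes,
                    "cluster": p.clusters.to_numpy(),
                    "clonality": p.cells["clonality"].to_numpy(),
                    "burden": det,
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    labeled = cells[cells["clonality"].isin(["HC", "LC"])]

    rows = []
    pvals, pidx = [], []
    for cluster, grp in labeled.groupby("cluster"):
        hc = grp.loc[grp["clonality"] == "HC", "burden"].to_numpy()
        lc = grp.loc[grp["clonality"] == "LC", "burden"].to_numpy()
        row = {
            "cluster": cluster,
            "hc_mean": hc.mean() if len(hc) else np.nan,
            "hc_sd": hc.std(ddof=1) if len(hc) > 1 else np.nan,
            "hc_n": len(hc),
            "lc_mean": lc.mean() if len(lc) else np.nan,
            "lc_sd": lc.std(ddof=1) if len(lc) > 1 else np.nan,
            "lc_n": len(lc),
            "p_value": np.nan,
        }
        if len(hc) and len(lc):
            row["p_value"] = mann_whitney(hc, lc).p_value
            pvals.append(row["p_value"])
            pidx.append(len(rows))
        else:
            log.warning("cluster %s lacks one clonality class; test skipped", cluster)
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary["p_adj"] = np.nan
    if pvals:
        adj = bh_adjust(np.array(pvals))
        for k, i in enumerate(pidx):
            summary.loc[i, "p_adj"] = adj[k]
    return cells, summary


def lc_hc_differential(
    patients: list[PatientCells],
    panel: ICPPanel | None = None,
    min_cells: int = 10,
    patient_aggregate: str = "median-of-log2fc",
) -> pd.DataFrame:
    """Cluster × checkpoint map of HC-over-LC expression fold changes.

    Per (patient, cluster, gene): log2FC = log2(mean(expm1 over HC) + 1) −
    log2(mean(expm1 over LC) + 1); a patient contributes to a cluster only
    when both classes have at least ``min_cells`` cells there. The reported
    value is the median over contributing patients (default), or the log2
    ratio of cross-patient median means under ``"log2-of-median-ratio"``.
    Cells missing everywhere yield NaN.
    """
    panel = panel or ICPPanel()
    per_patient: dict[tuple, dict[str, float]] = {}
    contrib: dict[tuple, list] = {}
    for p in patients:
        genes = panel.present_in(p.norm)
        gidx = p.norm.gene_index(genes)
        clon = p.cells["clonality"].to_numpy()
        clusters = p.clusters.to_numpy()
        for cluster in pd.unique(clusters[pd.notna(clusters)]):
            hc = np.flatnonzero((clusters == cluster) & (clon == "HC"))
            lc = np.flatnonzero((clusters == cluster) & (clon == "LC"))
            if len(hc) < min_cells or len(lc) < min_cells:
                continue
            mh = np.asarray(p.norm.values[hc][:, gidx].expm1().mean(axis=0)).ravel()
            ml = np.asarray(p.norm.values[lc][:, gidx].expm1().mean(axis=0)).ravel()
            for g, a, b in zip(genes, mh, ml):
                contrib.setdefault((cluster, g), []).append((a, b))
    rows: dict = {}
    for (cluster, g), pairs in contrib.items():
        if patient_aggregate == "median-of-log2fc":
            vals = [np.log2(a + 1) - np.log2(b + 1) for a, b in pairs]
            rows.setdefault(cluster, {})[g] = float(np.median(vals))
        elif patient_aggregate == "log2-of-median-ratio":
            a = np.median([a for a, _ in pairs])
            b = np.median([b for _, b in pairs])
            rows.setdefault(cluster, {})[g] = float(np.log2(a + 1) - np.log2(b + 1))
        else:
            raise ValueError(f"unknown aggregate {patient_aggregate!r}")
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.reindex(columns=[g for g in panel.genes if g in out.columns])
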