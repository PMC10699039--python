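"""Clonotype calling and repertoire statistics from 10x-style contig tables.

A clonotype is the sorted multiset of (chain, V gene, J gene, CDR3
nucleotide) over a cell's *productive* contigs — the strict key, so cells
sharing only one chain of a pair are distinct clonotypes. Keys are
patient-scoped: identical chains in two patients never share an identifier.
Clones of ≥3 cells are "high clonality" (HC); 1–2 cells are LC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SIZE_CLASSES",
    "HC_MIN_CLONE",
    "ClonotypeTable",
    "call_clonotypes",
    "repertoire_metrics",
    "clonotype_sharing",
]

#: clone-size classes; the 3-cell boundary is the HC/LC split
SIZE_CLASSES = ["1", "2", "3-10", "11-100", ">100"]
SIZE_CLASS_EDGES = [(1, 1), (2, 2), (3, 10), (11, 100), (101, np.inf)]
HC_MIN_CLONE = 3

VALID_CHAINS = {"TRA", "TRB"}

_KEY_FIELDS = {
    "strict": ("chain", "v_gene", "j_gene", "cdr3_nt"),
    "gene": ("chain", "v_gene", "j_gene"),
    "aa": ("chain", "cdr3"),
    "nt": ("chain", "cdr3_nt"),
}


@dataclass
class ClonotypeTable:
    """Per-cell clonotype assignment for one patient."""

    patient: str
    cells: pd.DataFrame
    # columns: barcode, clonotype_id, n_productive_chains, clone_size,
    #          clonality (HC/LC/none), size_class

    def clone_sizes(self) -> pd.Series:
        """Unique clonotype → number of cells."""
        with_ct = self.cells.dropna(subset=["clonotype_id"])
        return with_ct.groupby("clonotype_id").size()


def size_class(n: int) -> str:
    for name, (lo, hi) in zip(SIZE_CLASSES, SIZE_CLASS_EDGES):
        if lo <= n <= hi:
            return name
    raise ValueError(f"invalid clone size {n}")


def call_clonotypes(
    contigs: pd.DataFrame,
    patient: str,
    barcodes: list[str] | None = None,
    key_mode: str = "strict",
) -> ClonotypeTable:
    """Assign patient-scoped clonotype ids from a contig annotation table.

    ``barcodes``, when given, restricts the call to cells present in the
    expression matrix; unmatched contig barcodes are dropped and logged.
    Rows with malformed chain values are rejected with a log message.
    Cells with no productive contig get no clonotype (clonality "none").
    """
    if key_mode not in _KEY_FIELDS:
        raise ValueError(f"unknown clonotype key mode {key_mode!r}")
    fields = _KEY_FIELDS[key_mode]

    df = contigs.copy()
    bad_chain = ~df["chain"].isin(VALID_CHAINS)
    if bad_chain.any():
        log.warning("%s: rejected %d contig rows with malformed chain values",
                    patient, int(bad_chain.sum()))
        df = df[~bad_chain]
    if barcodes is not None:
        known = set(barcodes)
        unmatched = ~df["barcode"].isin(known)
        if unmatched.any():
            log.info("%s: dropped %d contigs with barcodes absent from the "
                     "count matrix", patient, int(unmatched.sum()))
            df = df[~unmatched]

    productive = df[df["productive"].astype(str).str.lower().isin(["true", "t", "1"])]

    keys: dict[str, tuple] = {}
    n_chains: dict[str, int] = {}
    for bc, grp in productive.groupby("barcode", sort=False):
        parts = sorted(tuple(row[f] for f in fields) for _, row in grp.iterrows())
        keys[bc] = tuple(parts)
        n_chains[bc] = len(parts)

    key_to_id: dict[tuple, str] = {}
    assignments: dict[str, str] = {}
    for bc in sorted(keys):  # deterministic id numbering under row shuffles
        key = keys[bc]
        if key not in key_to_id:
            key_to_id[key] = f"{patient}_ct{len(key_to_id) + 1}"
        assignments[bc] = key_to_id[key]

    universe = barcodes if barcodes is not None else sorted(
        set(contigs["barcode"]) | set(assignments)
    )
    rows = []
    id_counts = pd.Series(assignments).value_counts()
    for bc in universe:
        cid = assignments.get(bc)
        size = int(id_counts[cid]) if cid else 0
        rows.append(
            {
                "barcode": bc,
                "clonotype_id": cid,
                "n_productive_chains": n_chains.get(bc, 0),
                "clone_size": size if cid else 0,
                "clonality": ("HC" if size >= HC_MIN_CLONE else "LC") if cid else "none",
                "size_class": size_class(size) if cid else None,
            }
        )
    return ClonotypeTable(patient=patient, cells=pd.DataFrame(rows))


def repertoire_metrics(
    tables: list[ClonotypeTable],
    clusters: dict[str, pd.Series] | pd.Series,
    lineages: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Diversity and expansion summaries.

    Returns per (patient × cluster): unique clonotype count, percent of
    cells with a productive TCR, and clone-size-class composition; and per
    lineage (via the cluster → lineage map) the percent of clonotyped cells
    in expanded (≥3-cell) clones.
    """
    per_cluster_rows = []
    lineage_acc: dict[str, list[int]] = {}
    for table in tables:
        pat = table.patient
        cl = clusters[pat] if isinstance(clusters, dict) else clusters
        cells = table.cells.set_index("barcode")
        cl = cl.reindex(cells.index)
        if cl.isna().any():
            raise ValueError(f"{pat}: cluster labels missing for some cells")
        for cluster_id, idx in cl.groupby(cl).groups.items():
            sub = cells.loc[idx]
            with_ct = sub.dropna(subset=["clonotype_id"])
            row = {
                "patient": pat,
                "cluster": cluster_id,
                "n_cells": len(sub),
                "n_clonotypes": int(with_ct["clonotype_id"].nunique()),
                "pct_productive": 100.0 * len(with_ct) / len(sub) if len(sub) else 0.0,
            }
            class_counts = (
                with_ct.drop_duplicates("clonotype_id")["size_class"]
                .value_counts()
                .reindex(SIZE_CLASSES, fill_value=0)
            )
            for name in SIZE_CLASSES:
                row[f"clonotypes_{name}"] = int(class_counts[name])
            per_cluster_rows.append(row)

            if lineages is not None:
                lin = lineages.get(cluster_id) or lineages.get(str(cluster_id))
                if lin is not None:
                    lineage_acc.setdefault(lin, []).extend(
                        (with_ct["clone_size"] >= HC_MIN_CLONE).astype(int).tolist()
                    )

    out = {"per_cluster": pd.DataFrame(per_cluster_rows)}
    if lineages is not None:
        out["per_lineage"] = pd.DataFrame(
            [
                {
                    "lineage": lin,
                    "n_cells": len(flags),
                    "pct_expanded": 100.0 * float(np.mean(flags)) if flags else np.nan,
                }
                for lin, flags in sorted(lineage_acc.items())
            ]
        )
    return out


def clonotype_sharing(
    tables: list[ClonotypeTable],
    clusters: dict[str, pd.Series] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of clonotypes seen in ≥2 clusters, and the pairwise flows.

    Sharing is always within-patient (clonotype keys are patient-scoped).
    Returns (summary, flows): the summary has one row per patient plus a
    pooled row; the flow table lists (patient, clonotype, cluster_a,
    cluster_b, n_cells_a, n_cells_b) for Sankey-style diagram export.
    """
    summary_rows = []
    flow_rows = []
    total_shared = total_clonotypes = 0
    for table in tables:
        pat = table.patient
        cl = clusters[pat] if isinstance(clusters, dict) else clusters
        cells = table.cells.dropna(subset=["clonotype_id"]).set_index("barcode")
        cell_clusters = cl.reindex(cells.index)
        by_ct = cell_clusters.groupby(cells["clonotype_id"])
        n_ct = by_ct.ngroups
        shared = 0
        for cid, grp in by_ct:
            counts = grp.value_counts()
            if len(counts) >= 2:
                shared += 1
                seen = sorted(counts.index.astype(str))
                for i in range(len(seen)):
                    for j in range(i + 1, len(seen)):
                        flow_rows.append(
                            {
                                "patient": pat,
                                "clonotype_id": cid,
                                "cluster_a": seen[i],
                                "cluster_b": seen[j],
                                "n_cells_a": int(counts[counts.index.astype(str) == seen[i]].iloc[0]),
                                "n_cells_b": int(counts[counts.index.astype(str) == seen[j]].iloc[0]),
                            }
                        )
        summary_rows.append(
            {"patient": pat, "n_clonotypes": n_ct, "n_shared": shared,
             "pct_shared": 100.0 * shared / n_ct if n_ct else np.nan}
        )
        total_shared += shared
        total_clonotypes += n_ct
    summary_rows.append(
        {
            "patient": "pooled",
            "n_clonotypes": total_clonotypes,
            "n_shared": total_shared,
            "pct_shared": 100.0 * total_shared / total_clonotypes
            if total_clonotypes
            else np.nan,
        }
    )
    return pd.DataFrame(summary_rows), pd.DataFrame(
        flow_rows,
        columns=["patient", "clonotype_id", "cluster_a", "cluster_b",
                 "n_cells_a", "n_cells_b"],
    )
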