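"""Readers and writers for the standard on-disk formats.

Count matrices travel as MatrixMarket coordinate files (1-based indices)
in the 10x layout — ``matrix.mtx`` stored genes × cells with sidecar
``features.tsv`` / ``barcodes.tsv`` — TCR annotations as
``filtered_contig_annotations.csv`` with the 10x column names, flow samples
as one-row-per-cell CSV, and generator ground truth as JSON. All writers
round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .flow import MarkerMatrix
from .simulate import CountMatrix, FlowTruth, ScTruth

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_contigs",
    "read_contigs",
    "write_flow_csv",
    "read_flow_csv",
    "write_flow_truth",
    "write_sc_truth",
]

REQUIRED_CONTIG_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive",
]


def write_count_matrix(cm: CountMatrix, outdir: str | Path) -> Path:
    """Write matrix.mtx + barcodes.tsv + features.tsv (genes × cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", cm.counts.T.tocoo(), field="integer")
    pd.Series(cm.barcodes).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.DataFrame(
        {"gene_id": cm.genes, "gene_symbol": cm.genes, "kind": "Gene Expression"}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    return outdir


def read_count_matrix(indir: str | Path, patient: str) -> CountMatrix:
    """Read the 10x-layout MTX trio; duplicate gene symbols are summed."""
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    with open(mtx_path) as fh:
        header = fh.readline()
    if not header.startswith("%%MatrixMarket"):
        raise ValueError(f"{mtx_path}: malformed MatrixMarket header at line 1: "
                         f"{header.strip()!r}")
    mat = spio.mmread(mtx_path).tocsr().T.tocsr()  # → cells × genes
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].tolist()
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    genes = features[1].tolist()

    if len(set(genes)) != len(genes):
        sym = pd.Series(genes)
        groups = sym.groupby(sym).ngroup()
        uniq = sym.drop_duplicates().tolist()
        agg = sparse.csr_matrix(
            (np.ones(len(genes)), (np.arange(len(genes)), groups.to_numpy())),
            shape=(len(genes), len(uniq)),
        )
        mat = (mat @ agg).tocsr()
        genes = uniq
    return CountMatrix(
        patient=patient,
        counts=mat.astype(np.int64),
        barcodes=barcodes,
        genes=genes,
    )


def write_contigs(contigs: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    contigs.to_csv(path, index=False)
    return path


def read_contigs(path: str | Path) -> pd.DataFrame:
    """Tolerant contig reader: unknown extra columns are preserved."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: contig table missing required columns {missing}")
    return df


def write_flow_csv(m: MarkerMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, index=False, float_format="%.6g")
    return path


def read_flow_csv(path: str | Path, sample_id: str) -> MarkerMatrix:
    values = pd.read_csv(path)
    return MarkerMatrix(sample_id=sample_id, values=values)


def write_flow_truth(truth: FlowTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "sample_id": truth.sample_id,
        "subset": truth.subset.tolist(),
        "icp_positive": {c: truth.icp_positive[c].astype(int).tolist()
                         for c in truth.icp_positive.columns},
        "planted_positivity": truth.planted_positivity,
    }
    path.write_text(json.dumps(payload))
    return path


def write_sc_truth(truth: ScTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "patient": truth.patient,
        "planted_icp_effect": truth.planted_icp_effect,
        "clone_size_law": truth.clone_size_law,
        "cells": truth.cells.astype(object).where(truth.cells.notna(), None)
        .to_dict(orient="list"),
    }
    path.write_text(json.dumps(payload))
    return path
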