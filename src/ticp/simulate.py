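"""Synthetic cohorts with known ground truth.

Two generators emulate the statistical structure the analysis assumes:

* :func:`generate_flow_cohort` — per-sample cell × marker fluorescence
  tables. Each cell belongs to a latent subset (CD8, CD4FoxP3neg,
  CD4FoxP3pos, DP, DN, or non-T contaminant); every marker is drawn from a
  two-component log-normal (negative vs positive population), with
  checkpoint positivity probabilities that are subset-specific and strongly
  skewed toward the CD4+FoxP3+ regulatory subset. Defaults reproduce the
  study-cohort median T-cell composition (36.5% CD8, 38.6% CD4FoxP3−,
  9.5% CD4FoxP3+ of T-cells) and 82.2% CD39 positivity on Tregs.

* :func:`generate_sc_cohort` — per-patient sparse UMI count matrices with
  paired 10x-style TCR contig annotations. Counts are negative-binomial
  with cluster-specific marker-gene programs; clonotypes are patient-private
  with zero-truncated geometric clone sizes per lineage (more expansion in
  CD8 clusters: defaults target 72.2% of CD8 vs 23.7% of CD4 cells in
  clones of ≥3), and expanded FoxP3+ clones receive a planted log2
  fold-change on the checkpoint genes, which is the association the
  clonality × expression stratification is designed to detect.

Both generators return ground truth (per-cell labels, clonotype sizes,
planted rates) index-aligned with the emitted matrices, for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import sparse

from . import ICP_GENES, ICP_PROTEINS, LINEAGE_MARKERS
from .flow import GatingThresholds, MarkerMatrix

__all__ = [
    "FlowSimConfig",
    "ScSimConfig",
    "FlowTruth",
    "ScTruth",
    "CountMatrix",
    "generate_flow_cohort",
    "generate_sc_cohort",
    "true_thresholds",
    "DEFAULT_ICP_POSITIVITY",
]

FLOW_SUBSETS = ["CD8", "CD4FoxP3neg", "CD4FoxP3pos", "DP", "DN", "nonT"]

# which lineage markers each subset is positive for
_LINEAGE_POSITIVITY: dict[str, set[str]] = {
    "CD8": {"CD45", "CD3", "CD8"},
    "CD4FoxP3neg": {"CD45", "CD3", "CD4"},
    "CD4FoxP3pos": {"CD45", "CD3", "CD4", "FoxP3"},
    "DP": {"CD45", "CD3", "CD4", "CD8"},
    "DN": {"CD45", "CD3"},
    "nonT": set(),  # half the contaminants additionally stain CD45+
}

#: default checkpoint positivity per subset; the regulatory subset carries
#: the co-expression skew (CD39 at the cohort-median 0.822)
DEFAULT_ICP_POSITIVITY: dict[str, dict[str, float]] = {
    "CD8": {
        "CD25": 0.05, "CD28": 0.55, "CD39": 0.30, "4-1BB": 0.08, "CTLA-4": 0.08,
        "ICOS": 0.15, "OX40": 0.05, "PD-1": 0.45, "PD-L1": 0.08, "TIGIT": 0.40,
    },
    "CD4FoxP3neg": {
        "CD25": 0.20, "CD28": 0.85, "CD39": 0.20, "4-1BB": 0.05, "CTLA-4": 0.20,
        "ICOS": 0.30, "OX40": 0.20, "PD-1": 0.30, "PD-L1": 0.08, "TIGIT": 0.30,
    },
    "CD4FoxP3pos": {
        "CD25": 0.80, "CD28": 0.90, "CD39": 0.822, "4-1BB": 0.30, "CTLA-4": 0.60,
        "ICOS": 0.65, "OX40": 0.50, "PD-1": 0.45, "PD-L1": 0.15, "TIGIT": 0.70,
    },
    "DP": {p: 0.10 for p in ICP_PROTEINS} | {"CD28": 0.60},
    "DN": {p: 0.05 for p in ICP_PROTEINS} | {"CD28": 0.30},
    "nonT": {p: 0.05 for p in ICP_PROTEINS},
}

# T-cell-internal proportions 36.5/38.6/9.5/3.0/12.4 scaled by 85% T purity
_DEFAULT_SUBSET_PROPS = {
    "CD8": 0.365 * 0.85,
    "CD4FoxP3neg": 0.386 * 0.85,
    "CD4FoxP3pos": 0.095 * 0.85,
    "DP": 0.030 * 0.85,
    "DN": 0.124 * 0.85,
    "nonT": 0.15,
}

_ALL_MARKERS = LINEAGE_MARKERS + ICP_PROTEINS


class FlowSimConfig(BaseModel):
    """Parameters of the flow-cytometry cohort generator."""

    model_config = ConfigDict(extra="forbid")

    n_samples: int = Field(default=10, ge=1)
    cells_per_sample: int = Field(default=5000, ge=1)
    subset_props: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_SUBSET_PROPS)
    )
    icp_positivity: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_ICP_POSITIVITY.items()}
    )
    pos_mean: dict[str, float] = Field(
        default_factory=lambda: {m: 5000.0 for m in _ALL_MARKERS}
    )
    neg_mean: dict[str, float] = Field(
        default_factory=lambda: {m: 50.0 for m in _ALL_MARKERS}
    )
    noise_sd: float = Field(default=0.5, gt=0)  # log-space dispersion
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        total = sum(self.subset_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subset_props must sum to 1 (got {total})")
        unknown = set(self.subset_props) - set(FLOW_SUBSETS)
        if unknown:
            raise ValueError(f"unknown subsets in subset_props: {sorted(unknown)}")
        for s, table in self.icp_positivity.items():
            for icp, p in table.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"icp_positivity[{s}][{icp}] outside [0, 1]")
        return self


@dataclass
class FlowTruth:
    """Ground truth for one generated flow sample."""

    sample_id: str
    subset: pd.Series  # per-cell planted subset label
    icp_positive: pd.DataFrame  # per-cell boolean draw per checkpoint
    planted_positivity: dict[str, dict[str, float]]


def true_thresholds(config: FlowSimConfig) -> GatingThresholds:
    """Valley cutoffs for the generator's two log-normal populations.

    The midpoint of the component means in log space, i.e. the geometric
    mean of the negative and positive location parameters.
    """
    return GatingThresholds(
        {
            m: float(np.sqrt(config.neg_mean[m] * config.pos_mean[m]))
            for m in _ALL_MARKERS
        }
    )


def generate_flow_cohort(
    config: FlowSimConfig | None = None,
) -> list[tuple[MarkerMatrix, FlowTruth]]:
    """Draw a cohort of flow samples from the two-component log-normal model."""
    config = config or FlowSimConfig()
    subsets = [s for s in FLOW_SUBSETS if s in config.subset_props]
    props = np.array([config.subset_props[s] for s in subsets])
    streams = np.random.SeedSequence(config.seed).spawn(config.n_samples)

    cohort = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sample_id = f"S{i + 1:02d}"
        n = config.cells_per_sample
        labels = rng.choice(subsets, size=n, p=props)

        positive = pd.DataFrame(False, index=range(n), columns=_ALL_MARKERS)
        for s in subsets:
            mask = labels == s
            k = int(mask.sum())
            if k == 0:
                continue
            for m in LINEAGE_MARKERS:
                positive.loc[mask, m] = m in _LINEAGE_POSITIVITY[s]
            if s == "nonT":  # half of contaminants are CD45+ non-T immune cells
                positive.loc[mask, "CD45"] = rng.random(k) < 0.5
            table = config.icp_positivity.get(s, {})
            for m in ICP_PROTEINS:
                positive.loc[mask, m] = rng.random(k) < table.get(m, 0.0)

        values = pd.DataFrame(index=range(n), columns=_ALL_MARKERS, dtype=float)
        for m in _ALL_MARKERS:
            loc = np.where(positive[m], config.pos_mean[m], config.neg_mean[m])
            values[m] = np.exp(np.log(loc) + config.noise_sd * rng.standard_normal(n))

        matrix = MarkerMatrix(sample_id=sample_id, values=values)
        truth = FlowTruth(
            sample_id=sample_id,
            subset=pd.Series(labels, name="subset"),
            icp_positive=positive[ICP_PROTEINS].copy(),
            planted_positivity=config.icp_positivity,
        )
        cohort.append((matrix, truth))
    return cohort


# --------------------------------------------------------------------------
# scRNA-seq + TCR cohort
# --------------------------------------------------------------------------

SC_CLUSTERS = ["CD8_EM", "CD8_EX", "CD4_EM", "TREG"]

_DEFAULT_CLUSTER_PROPS = {"CD8_EM": 0.30, "CD8_EX": 0.25, "CD4_EM": 0.28, "TREG": 0.17}
_DEFAULT_CLUSTER_LINEAGE = {"CD8_EM": "CD8", "CD8_EX": "CD8", "CD4_EM": "CD4", "TREG": "CD4"}

#: per-cluster upregulated gene programs, effects in log2 units; the
#: regulatory program carries 8/10 checkpoint genes (not PDCD1 / CD274)
_DEFAULT_MARKER_PROGRAMS: dict[str, dict[str, float]] = {
    "CD8_EM": {"CD8A": 6.0, "CD8B": 6.0, "GZMK": 6.0, "IL7R": 4.0, "STAT4": 4.0},
    "CD8_EX": {
        "CD8A": 6.0, "CD8B": 6.0, "PDCD1": 6.0, "HAVCR2": 5.0, "LAG3": 5.0,
        "TIGIT": 4.0, "CTLA4": 3.0, "GZMB": 4.0, "TOX": 4.0,
    },
    "CD4_EM": {"CD4": 6.0, "IL7R": 6.0, "CD28": 3.0, "CCR7": 4.0},
    "TREG": {
        "CD4": 6.0, "FOXP3": 7.0, "IL2RA": 6.0, "ENTPD1": 6.0, "CTLA4": 6.0,
        "ICOS": 6.0, "TNFRSF4": 6.0, "TIGIT": 6.0, "TNFRSF9": 4.0, "CD28": 3.0,
    },
}

# zero-truncated geometric success parameters solved so that the expected
# cell-level fraction in clones of >= 3 cells is 0.722 (CD8) / 0.237 (CD4)
_DEFAULT_CLONE_LAW = {"CD8": 0.3472477221777080, "CD4": 0.6835829939253610}

MARKER_GENES = [
    "CD3D", "CD3E", "CD3G", "CD4", "CD8A", "CD8B", "IL7R", "FOXP3",
    "GZMK", "GZMB", "GNLY", "PRF1", "STAT4", "HAVCR2", "LAG3", "TOX",
    "CCR7", "SELL",
]
MITO_GENES = ["MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2", "MT-ND3",
              "MT-ND4", "MT-ATP6"]
#: small cell-cycle signature subset so phase scoring has genes to work with
CC_S_GENES_SIM = ["MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4"]
CC_G2M_GENES_SIM = ["HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2"]


class ScSimConfig(BaseModel):
    """Parameters of the scRNA-seq + TCR cohort generator."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=5, ge=1)
    cells_per_patient: int = Field(default=5000, ge=1)
    cluster_props: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CLUSTER_PROPS)
    )
    cluster_lineage: dict[str, str] = Field(
        default_factory=lambda: dict(_DEFAULT_CLUSTER_LINEAGE)
    )
    marker_programs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {c: dict(p) for c, p in _DEFAULT_MARKER_PROGRAMS.items()}
    )
    marker_base_mean: float = Field(default=0.3, gt=0)
    icp_base_mean: float = Field(default=0.15, gt=0)
    n_filler_genes: int = Field(default=260, ge=0)
    filler_log_mean: float = 1.4  # ln-space location of filler gene means
    filler_log_sd: float = Field(default=1.0, ge=0)
    mito_mean: float = Field(default=15.0, gt=0)
    nb_dispersion: float = Field(default=1.0, gt=0)  # NB shape; var = mu + mu^2/theta
    gene_dispersion: dict[str, float] = Field(default_factory=dict)  # overrides
    library_size_sigma: float = Field(default=0.3, ge=0)
    clone_size_law: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CLONE_LAW)
    )
    clonotype_sharing_rate: float = Field(default=0.054, ge=0, le=1)
    p_productive: float = Field(default=0.84, ge=0, le=1)
    planted_icp_effect: float = 1.0  # log2 FC on checkpoint genes in expanded Tregs
    extra_genes: dict[str, float] = Field(default_factory=dict)  # symbol -> base mean
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.cluster_props:
            raise ValueError("cluster_props must not be empty")
        total = sum(self.cluster_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster_props must sum to 1 (got {total})")
        for c in self.cluster_props:
            if c not in self.cluster_lineage:
                raise ValueError(f"cluster {c!r} has no lineage assignment")
            if self.cluster_lineage[c] not in self.clone_size_law:
                raise ValueError(f"no clone-size law for lineage of cluster {c!r}")
        for lin, p in self.clone_size_law.items():
            if not (0 < p <= 1):
                raise ValueError(f"clone_size_law[{lin}] must be in (0, 1]")
        return self

    def gene_universe(self) -> tuple[list[str], np.ndarray]:
        """Gene symbols and their baseline negative-binomial means."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xFEED]))
        genes, means = [], []
        for g in MARKER_GENES:
            genes.append(g)
            means.append(self.marker_base_mean)
        for g in ICP_GENES:
            genes.append(g)
            means.append(self.icp_base_mean)
        for g in MITO_GENES:
            genes.append(g)
            means.append(self.mito_mean)
        for g in CC_S_GENES_SIM + CC_G2M_GENES_SIM:
            genes.append(g)
            means.append(0.1)
        for j in range(self.n_filler_genes):
            genes.append(f"GENE{j + 1:04d}")
            means.append(float(np.exp(self.filler_log_mean
                                      + self.filler_log_sd * rng.standard_normal())))
        for g, mu in self.extra_genes.items():
            genes.append(g)
            means.append(float(mu))
        return genes, np.array(means)


@dataclass
class CountMatrix:
    """Sparse cells × genes UMI counts for one patient."""

    patient: str
    counts: sparse.csr_matrix  # cells × genes, integer
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique within a patient")
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape inconsistent with barcodes/genes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ScTruth:
    """Ground truth for one generated scRNA-seq patient."""

    patient: str
    cells: pd.DataFrame  # barcode, cluster, lineage, clonotype_id, clone_size, expanded
    planted_icp_effect: float
    clone_size_law: dict[str, float] = field(default_factory=dict)


def _draw_clone_sizes(rng: np.random.Generator, n_cells: int, p: float) -> list[int]:
    """Zero-truncated geometric clone sizes covering exactly n_cells cells."""
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        s = int(rng.geometric(p))
        if total + s > n_cells:
            s = n_cells - total
        sizes.append(s)
        total += s
    return sizes


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _random_cdr3(rng: np.random.Generator) -> tuple[str, str]:
    """In-frame stop-free CDR3: (nt, aa); length 30–45 nt."""
    n_codons = int(rng.integers(10, 16))  # 30..45 nt
    codons = rng.choice(_SENSE_CODONS, size=n_codons)
    nt = "".join(codons)
    aa = "".join(_CODON_TABLE[c] for c in codons)
    return nt, aa


def _random_chain(rng: np.random.Generator, chain: str) -> dict[str, str]:
    if chain == "TRA":
        v = f"TRAV{int(rng.integers(1, 41))}"
        j = f"TRAJ{int(rng.integers(1, 51))}"
    else:
        v = f"TRBV{int(rng.integers(1, 31))}"
        j = f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 8))}"
    nt, aa = _random_cdr3(rng)
    return {"chain": chain, "v_gene": v, "j_gene": j, "cdr3": "C" + aa + "F",
            "cdr3_nt": "TGT" + nt + "TTT"}


_CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id", "raw_consensus_id",
]


def generate_sc_cohort(
    config: ScSimConfig | None = None,
) -> list[tuple[CountMatrix, pd.DataFrame, ScTruth]]:
    """Draw (CountMatrix, contig table, truth) for each synthetic patient.

    Clonotype identifiers are patient-scoped and never reused across
    patients; contig tables follow the 10x filtered_contig_annotations
    column layout.
    """
    config = config or ScSimConfig()
    genes, base_means = config.gene_universe()
    clusters = list(config.cluster_props)
    props = np.array([config.cluster_props[c] for c in clusters])
    icp_idx = np.array([genes.index(g) for g in ICP_GENES if g in genes])
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    cohort = []
    for pi, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        patient = f"P{pi + 1}"
        n = config.cells_per_patient

        cluster = rng.choice(clusters, size=n, p=props)
        barcodes = _draw_barcodes(rng, n)

        # -- clonotypes (productive cells only, clones drawn per cluster) --
        productive = rng.random(n) < config.p_productive
        clonotype = np.full(n, None, dtype=object)
        clone_size = np.zeros(n, dtype=int)
        clone_defs: dict[str, dict] = {}
        next_id = 1
        for c in clusters:
            lin = config.cluster_lineage[c]
            idx = np.flatnonzero((cluster == c) & productive)
            rng.shuffle(idx)
            offset = 0
            for s in _draw_clone_sizes(rng, len(idx), config.clone_size_law[lin]):
                cid = f"{patient}_clonotype{next_id}"
                next_id += 1
                members = idx[offset : offset + s]
                offset += s
                clonotype[members] = cid
                clone_size[members] = s
                clone_defs[cid] = {
                    "lineage": lin,
                    "chains": [_random_chain(rng, "TRA"), _random_chain(rng, "TRB")],
                }

        # -- plant clonotype sharing: move one cell of some multi-cell clones
        #    into another cluster of the same lineage --
        multi = [cid for cid, d in clone_defs.items()
                 if np.sum(clonotype == cid) >= 2]
        n_shared = int(round(config.clonotype_sharing_rate * len(clone_defs)))
        rng.shuffle(multi)
        for cid in multi[:n_shared]:
            lin = clone_defs[cid]["lineage"]
            targets = [c for c in clusters
                       if config.cluster_lineage[c] == lin]
            members = np.flatnonzero(clonotype == cid)
            cell = members[0]
            others = [c for c in targets if c != cluster[cell]]
            if others:
                cluster[cell] = others[int(rng.integers(len(others)))]

        expanded = clone_size >= 3

        # -- expression: NB means per cell from cluster programs --
        log2fc = np.zeros((n, len(genes)))
        for c, program in config.marker_programs.items():
            mask = cluster == c
            for g, eff in program.items():
                if g in genes:
                    log2fc[mask, genes.index(g)] += eff
        if config.planted_icp_effect != 0 and "TREG" in clusters:
            boost = expanded & (cluster == "TREG")
            log2fc[np.ix_(boost, icp_idx)] += config.planted_icp_effect

        size_factor = np.exp(config.library_size_sigma * rng.standard_normal(n))
        mu = base_means[None, :] * (2.0 ** log2fc) * size_factor[:, None]
        theta = np.array(
            [config.gene_dispersion.get(g, config.nb_dispersion) for g in genes]
        )
        lam = rng.gamma(shape=theta[None, :], scale=mu / theta[None, :])
        counts = rng.poisson(lam)
        matrix = CountMatrix(
            patient=patient,
            counts=sparse.csr_matrix(counts, dtype=np.int64),
            barcodes=barcodes,
            genes=list(genes),
        )

        # -- contig table --
        rows = []
        for i in range(n):
            bc = barcodes[i]
            if clonotype[i] is not None:
                cid = clonotype[i]
                for k, ch in enumerate(clone_defs[cid]["chains"]):
                    rows.append(_contig_row(bc, f"{bc}_contig_{k + 1}", ch, True, cid))
            elif rng.random() < 0.6:  # orphan non-productive contig
                ch = _random_chain(rng, "TRA" if rng.random() < 0.5 else "TRB")
                rows.append(_contig_row(bc, f"{bc}_contig_1", ch, False, "None"))
        contigs = pd.DataFrame(rows, columns=_CONTIG_COLUMNS)

        cells = pd.DataFrame(
            {
                "barcode": barcodes,
                "cluster": cluster,
                "lineage": [config.cluster_lineage[c] for c in cluster],
                "clonotype_id": clonotype,
                "clone_size": clone_size,
                "expanded": expanded,
            }
        )
        truth = ScTruth(
            patient=patient,
            cells=cells,
            planted_icp_effect=config.planted_icp_effect,
            clone_size_law=dict(config.clone_size_law),
        )
        cohort.append((matrix, contigs, truth))
    return cohort


def _draw_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice(list("ACGT"), size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _contig_row(bc: str, contig_id: str, ch: dict, productive: bool, cid: str) -> dict:
    return {
        "barcode": bc,
        "is_cell": "True",
        "contig_id": contig_id,
        "high_confidence": "True",
        "length": 450 + len(ch["cdr3_nt"]),
        "chain": ch["chain"],
        "v_gene": ch["v_gene"],
        "d_gene": "None",
        "j_gene": ch["j_gene"],
        "c_gene": "TRAC" if ch["chain"] == "TRA" else "TRBC1",
        "full_length": "True",
        "productive": "True" if productive else "False",
        "cdr3": ch["cdr3"],
        "cdr3_nt": ch["cdr3_nt"],
        "reads": 1000,
        "umis": 4,
        "raw_clonotype_id": cid,
        "raw_consensus_id": "None",
    }
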