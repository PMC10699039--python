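"""Supervised flow-cytometry analysis of tumor-infiltrating T-cells.

Covers the gated view of the data: hierarchical subset assignment
(CD45 → CD3 → CD4/CD8/FoxP3), per-subset checkpoint positivity and mean
fluorescence intensity (MFI), the Treg/Tconv MFI-ratio summary, pairwise
checkpoint co-positivity, and the cohort-level group statistics
(Kruskal–Wallis + Dunn, Mann–Whitney).

Fluorescence values are arbitrary units as produced after compensation
(negative values allowed); positivity is always relative to explicit
per-marker cutoffs supplied as :class:`GatingThresholds`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupTestReport, dunn_test, mann_whitney

log = logging.getLogger(__name__)

__all__ = [
    "ICP_PANEL_PROTEINS",
    "GATING_MARKERS",
    "T_SUBSETS",
    "REPORTED_SUBSETS",
    "MarkerMatrix",
    "GatingThresholds",
    "SubsetProfile",
    "CoPositivityResult",
    "assign_subsets",
    "subset_fractions",
    "icp_profile",
    "mfi_ratio_heatmap",
    "co_positivity",
    "group_compare",
]

ICP_PANEL_PROTEINS = [
    "CD25", "CD28", "CD39", "4-1BB", "CTLA-4",
    "ICOS", "OX40", "PD-1", "PD-L1", "TIGIT",
]
GATING_MARKERS = ["CD45", "CD3", "CD4", "CD8", "FoxP3"]
#: all CD3+ subsets; fractions over these sum to 100 per sample
T_SUBSETS = ["CD8", "CD4FoxP3neg", "CD4FoxP3pos", "DP", "DN"]
#: the three subsets profiled for checkpoint expression
REPORTED_SUBSETS = ["CD8", "CD4FoxP3neg", "CD4FoxP3pos"]


@dataclass
class MarkerMatrix:
    """Cells × markers fluorescence table for one sample."""

    sample_id: str
    values: pd.DataFrame  # one row per cell, one column per marker
    marker_roles: dict[str, str] = field(default_factory=dict)  # marker -> lineage|icp
    panel: list[str] = field(default_factory=lambda: list(ICP_PANEL_PROTEINS))

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("marker matrix contains missing values")
        missing = [m for m in self.panel if m not in self.values.columns]
        if missing:
            raise ValueError(f"panel markers absent from matrix: {missing}")
        if not self.marker_roles:
            self.marker_roles = {
                m: ("icp" if m in self.panel else "lineage") for m in self.values.columns
            }

    @property
    def n_cells(self) -> int:
        return len(self.values)


@dataclass
class GatingThresholds:
    """Per-marker positivity cutoffs, in the same units as the values."""

    cutoffs: dict[str, float]

    def __post_init__(self):
        bad = [m for m, c in self.cutoffs.items() if not np.isfinite(c)]
        if bad:
            raise ValueError(f"non-finite cutoffs for markers: {bad}")

    def __getitem__(self, marker: str) -> float:
        if marker not in self.cutoffs:
            raise KeyError(f"no gating threshold for marker {marker!r}")
        return self.cutoffs[marker]


@dataclass
class SubsetProfile:
    """Checkpoint profile of one T-cell subset in one sample."""

    sample_id: str
    subset: str
    subset_fraction_of_T: float  # percent
    percent_positive: dict[str, float] = field(default_factory=dict)
    mfi: dict[str, float] = field(default_factory=dict)


@dataclass
class CoPositivityResult:
    icp_a: str
    icp_b: str
    double_positive_pct: dict[str, float]  # subset -> % positive for both
    foxp3_share_of_cd4_double_pos: float | None  # % FoxP3+ among CD4+ A+B+ cells


def assign_subsets(m: MarkerMatrix, g: GatingThresholds) -> pd.Series:
    """Hierarchical gating into T-cell subsets.

    CD45− or CD3− cells are ``nonT``; among T-cells, CD4/CD8 single
    positives split into CD8 and (by FoxP3) CD4FoxP3pos/neg, double
    positives are ``DP`` and double negatives ``DN``.
    """
    for marker in GATING_MARKERS:
        if marker not in m.values.columns:
            raise ValueError(f"gating marker {marker!r} missing from matrix")
        g[marker]  # raises KeyError if absent from the thresholds

    v = m.values
    cd45 = v["CD45"].to_numpy() > g["CD45"]
    cd3 = v["CD3"].to_numpy() > g["CD3"]
    cd4 = v["CD4"].to_numpy() > g["CD4"]
    cd8 = v["CD8"].to_numpy() > g["CD8"]
    foxp3 = v["FoxP3"].to_numpy() > g["FoxP3"]

    labels = np.full(len(v), "nonT", dtype=object)
    t = cd45 & cd3
    labels[t & cd8 & ~cd4] = "CD8"
    labels[t & cd4 & ~cd8 & foxp3] = "CD4FoxP3pos"
    labels[t & cd4 & ~cd8 & ~foxp3] = "CD4FoxP3neg"
    labels[t & cd4 & cd8] = "DP"
    labels[t & ~cd4 & ~cd8] = "DN"
    return pd.Series(labels, index=v.index, name="subset")


def subset_fractions(labels: pd.Series) -> pd.Series:
    """Percent of T-cells per subset; sums to 100 over the five subsets."""
    t = labels[labels != "nonT"]
    if len(t) == 0:
        raise ValueError("no T-cells after gating")
    counts = t.value_counts().reindex(T_SUBSETS, fill_value=0)
    return 100.0 * counts / len(t)


def icp_profile(
    m: MarkerMatrix, labels: pd.Series, g: GatingThresholds
) -> list[SubsetProfile]:
    """Percent-positive and MFI for each checkpoint in each reported subset.

    MFI is the arithmetic mean of raw (untransformed) fluorescence over the
    subset's cells. Subsets with no cells are omitted with a log warning.
    """
    fractions = subset_fractions(labels)
    profiles = []
    for subset in REPORTED_SUBSETS:
        mask = (labels == subset).to_numpy()
        if mask.sum() == 0:
            log.warning("sample %s: subset %s empty, omitted", m.sample_id, subset)
            continue
        sub = m.values.loc[mask]
        prof = SubsetProfile(
            sample_id=m.sample_id,
            subset=subset,
            subset_fraction_of_T=float(fractions[subset]),
        )
        for icp in m.panel:
            vals = sub[icp].to_numpy()
            prof.percent_positive[icp] = float(100.0 * np.mean(vals > g[icp]))
            prof.mfi[icp] = float(np.mean(vals))
        profiles.append(prof)
    return profiles


def mfi_ratio_heatmap(profiles: list[SubsetProfile]) -> pd.Series:
    """Per-checkpoint ratio of cohort-median Treg MFI over Tconv MFI.

    For each checkpoint: (median across samples of CD4FoxP3pos MFI) /
    (median across samples of CD4FoxP3neg MFI). A zero denominator yields
    +inf with a warning.
    """
    treg = [p for p in profiles if p.subset == "CD4FoxP3pos"]
    tconv = [p for p in profiles if p.subset == "CD4FoxP3neg"]
    if not treg or not tconv:
        raise ValueError("need at least one sample with both CD4 subsets profiled")
    panel = list(treg[0].mfi)
    out = {}
    for icp in panel:
        num = float(np.median([p.mfi[icp] for p in treg]))
        den = float(np.median([p.mfi[icp] for p in tconv]))
        if den == 0:
            log.warning("zero Tconv median MFI for %s; ratio reported as +inf", icp)
            out[icp] = np.inf
        else:
            out[icp] = num / den
    return pd.Series(out, name="treg_over_tconv_mfi_ratio")


def co_positivity(
    m: MarkerMatrix,
    labels: pd.Series,
    icp_a: str,
    icp_b: str,
    g: GatingThresholds,
) -> CoPositivityResult:
    """Pairwise checkpoint co-expression within the CD4 subsets.

    Reports (i) the percent of cells positive for both checkpoints within
    each reported subset and (ii) the percent of FoxP3+ cells among CD4+
    cells double-positive for the pair — the statistic behind using e.g.
    CD25+CD39+ as a surrogate Treg gate.
    """
    for icp in (icp_a, icp_b):
        if icp not in m.panel:
            raise ValueError(f"{icp!r} not in the checkpoint panel")
    pos_a = m.values[icp_a].to_numpy() > g[icp_a]
    pos_b = m.values[icp_b].to_numpy() > g[icp_b]
    double = pos_a & pos_b

    pct = {}
    for subset in REPORTED_SUBSETS:
        mask = (labels == subset).to_numpy()
        pct[subset] = float(100.0 * double[mask].mean()) if mask.sum() else np.nan

    cd4 = labels.isin(["CD4FoxP3neg", "CD4FoxP3pos"]).to_numpy()
    cd4_dp = cd4 & double
    if cd4_dp.sum() == 0:
        log.warning("no CD4+ %s+%s+ cells; FoxP3 share undefined", icp_a, icp_b)
        share = None
    else:
        foxp3pos = (labels == "CD4FoxP3pos").to_numpy()
        share = float(100.0 * foxp3pos[cd4_dp].mean())
    return CoPositivityResult(icp_a, icp_b, pct, share)


def group_compare(groups: dict[str, np.ndarray], paired: bool = False) -> GroupTestReport:
    """Cohort-level comparison of a statistic across groups.

    Two unpaired groups → Mann–Whitney U (exact at small n); more than two
    → Kruskal–Wallis omnibus followed by Dunn pairwise z-tests with
    Bonferroni-style adjustment. Two paired groups → Wilcoxon signed-rank.
    Empty groups are dropped with a warning.
    """
    kept = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    dropped = [k for k in groups if k not in kept]
    for k in dropped:
        log.warning("group %r has no observations; dropped", k)
    if len(kept) < 2:
        raise ValueError("need at least two non-empty groups")
    if sum(len(v) for v in kept.values()) < 2:
        raise ValueError("need at least two observations overall")

    if len(kept) == 2:
        (ka, va), (kb, vb) = kept.items()
        if paired:
            if len(va) != len(vb):
                raise ValueError("paired comparison requires equal-length groups")
            if np.all(va == vb):
                return GroupTestReport("wilcoxon-signed-rank", 0.0, 1.0,
                                       dropped_groups=dropped)
            stat, p = sps.wilcoxon(va, vb)
            return GroupTestReport("wilcoxon-signed-rank", float(stat), float(p),
                                   dropped_groups=dropped)
        res = mann_whitney(va, vb)
        return GroupTestReport("mann-whitney", res.u, res.p_value,
                               dropped_groups=dropped)

    dunn = dunn_test(kept)
    return GroupTestReport("kruskal-dunn", dunn.h, dunn.h_p_value, dunn=dunn,
                           dropped_groups=dropped)
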