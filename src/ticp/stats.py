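"""Nonparametric statistics used across the flow and single-cell stages.

Implements the rank tests the analysis relies on — Mann–Whitney U (exact
enumeration at small sample sizes, tie-corrected normal approximation
otherwise), Kruskal–Wallis followed by Dunn's multiple-comparison z-tests,
and Benjamini–Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MannWhitneyResult",
    "DunnResult",
    "GroupTestReport",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_test",
    "bh_adjust",
]

#: both group sizes at or below this use exact enumeration of the U null
EXACT_LIMIT = 8


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" | "asymptotic"
    n1: int
    n2: int


@dataclass
class DunnResult:
    """Pairwise Dunn z-tests following a Kruskal–Wallis omnibus test."""

    h: float
    h_p_value: float
    pairs: list[tuple[str, str]] = field(default_factory=list)
    z: list[float] = field(default_factory=list)
    p: list[float] = field(default_factory=list)
    p_adj: list[float] = field(default_factory=list)


@dataclass
class GroupTestReport:
    test: str  # "mann-whitney" | "kruskal-dunn"
    statistic: float
    p_value: float
    dunn: DunnResult | None = None
    dropped_groups: list[str] = field(default_factory=list)


def _rank_midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_statistic(ranks1: np.ndarray, n1: int) -> float:
    return float(ranks1.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration of all rank assignments (tie-safe, two-sided by
    distance of U from its null mean) when both groups have at most
    ``EXACT_LIMIT`` observations, otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rank_midranks(pooled)
    u = _u_statistic(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if n1 <= EXACT_LIMIT and n2 <= EXACT_LIMIT:
        # enumerate all C(n1+n2, n1) assignments of ranks to group 1
        n = n1 + n2
        d_obs = abs(u - mu)
        hits = 0
        for idx in _combinations(range(n), n1):
            u_perm = _u_statistic(ranks[list(idx)], n1)
            if abs(u_perm - mu) >= d_obs - 1e-9:
                hits += 1
        p = hits / comb(n, n1)
        return MannWhitneyResult(u, min(1.0, p), "exact", n1, n2)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u, 1.0, "asymptotic", n1, n2)
    # continuity correction toward the null mean
    num = abs(u - mu) - 0.5
    z = max(num, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return MannWhitneyResult(u, p, "asymptotic", n1, n2)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; (H, p).

    All-identical data (no between-group variance) yields H = 0, p = 1
    rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_test(groups: dict[str, np.ndarray]) -> DunnResult:
    """Dunn's multiple-comparison test after Kruskal–Wallis.

    Pairwise z = (mean rank difference) / SE with a shared tie correction;
    p-values adjusted by Bonferroni-style multiplication with the number of
    pairwise comparisons (classical Dunn adjustment).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    h, h_p = kruskal_wallis(arrays)
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _rank_midranks(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for name, arr in zip(names, arrays):
        k = len(arr)
        mean_ranks[name] = float(ranks[offset : offset + k].mean())
        sizes[name] = k
        offset += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))

    res = DunnResult(h=h, h_p_value=h_p)
    pairs = list(_combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        se2 = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2)
            p = float(2.0 * sps.norm.sf(abs(z)))
        res.pairs.append((a, b))
        res.z.append(float(z))
        res.p.append(p)
        res.p_adj.append(min(1.0, p * m))
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
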