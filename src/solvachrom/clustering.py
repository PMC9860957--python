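"""One-dimensional clustering of dyes by solvatochromic sensitivity A.

Dyes are partitioned into k ordered sensitivity classes on the single
coordinate A.  Cluster 1 always holds the largest (most positive) A values
and cluster k the most negative, following the convention that class 1 is
the strongly positively solvatochromic end.  Typical choices are k = 6
(coarse taxonomy) and k = 24 (fine).

Strategies: ``quantile`` (equal-frequency intervals, the default),
``equal_width`` (uniform intervals over the A range), and ``kmeans1d``
(exact dynamic-programming 1-D k-means, which is deterministic unlike the
general heuristic).  All are interval-based: each cluster occupies a
contiguous range of A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sensitivity import SensitivityResult
from .spectra_io import DyeSeries, to_wavenumber_point

logger = logging.getLogger(__name__)

STRATEGIES = ("quantile", "equal_width", "kmeans1d")


@dataclass(frozen=True)
class ClusterAssignment:
    """dye -> ordered sensitivity class (1 = highest A) for a chosen k."""

    dye_id: str
    k: int
    cluster_index: int
    A_value: float


def _kmeans_1d_boundaries(values: np.ndarray, k: int) -> list[int]:
    """Exact 1-D k-means on sorted values via dynamic programming.

    Returns the start indices of each cluster in the sorted array.
    O(k n^2) with prefix sums — fine for hundreds of dyes.
    """
    n = values.size
    pref = np.concatenate(([0.0], np.cumsum(values)))
    pref2 = np.concatenate(([0.0], np.cumsum(values**2)))

    def cost(i: int, j: int) -> float:
        # within-cluster sum of squares of values[i:j]
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        m = j - i
        return s2 - s * s / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = dp[c - 1, i] + cost(i, j)
                if v < best:
                    best, arg = v, i
            dp[c, j] = best
            back[c, j] = arg
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = back[c, j]
        bounds.append(i)
        j = i
    return bounds[::-1]


def cluster_by_A(
    results: Sequence[SensitivityResult],
    k: int,
    strategy: str = "quantile",
) -> list[ClusterAssignment]:
    """Partition dyes into k ordered clusters by their fitted A.

    Cluster indices are 1-based and descending in A (cluster 1 = highest).
    Ties in A are broken by dye_id lexical order, so assignments never
    depend on input ordering.  When all A values coincide, the partition is
    degenerate: every dye goes to cluster 1 with a warning.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; choose {STRATEGIES}")
    if len(results) < k:
        raise ValidationError(f"k={k} exceeds number of dyes ({len(results)})")

    # Sort descending in A, dye_id as tiebreak, so input order is irrelevant.
    ordered = sorted(results, key=lambda r: (-r.A_stokes, r.dye_id))
    A = np.array([r.A_stokes for r in ordered])

    if np.ptp(A) == 0:
        logger.warning("all A values identical; single-cluster fallback")
        return [
            ClusterAssignment(r.dye_id, k=k, cluster_index=1, A_value=r.A_stokes)
            for r in ordered
        ]

    n = len(ordered)
    if strategy == "quantile":
        # Equal-frequency split of the descending sequence.
        edges = [round(i * n / k) for i in range(k + 1)]
        labels = np.empty(n, dtype=int)
        for c in range(k):
            labels[edges[c] : edges[c + 1]] = c + 1
    elif strategy == "equal_width":
        lo, hi = A.min(), A.max()
        width = (hi - lo) / k
        # Descending A: cluster 1 covers the top interval.
        labels = np.minimum(((hi - A) / width).astype(int), k - 1) + 1
    else:  # kmeans1d on ascending values, then relabel descending
        asc = A[::-1]
        starts = _kmeans_1d_boundaries(asc, k)
        asc_labels = np.empty(n, dtype=int)
        bounds = starts + [n]
        for c in range(k):
            asc_labels[bounds[c] : bounds[c + 1]] = c  # 0 = lowest A
        labels = (k - asc_labels)[::-1]

    return [
        ClusterAssignment(r.dye_id, k=k, cluster_index=int(lab), A_value=r.A_stokes)
        for r, lab in zip(ordered, labels)
    ]


def cluster_summary(
    assignments: Sequence[ClusterAssignment],
    results: Sequence[SensitivityResult],
    series: Sequence[DyeSeries] | None = None,
) -> pd.DataFrame:
    """Per-cluster summary: n dyes, A min/mean/max, Stokes and QY ranges.

    Stokes-shift and quantum-yield ranges are pooled over the member dyes'
    records and need ``series``; without it those columns are NaN.
    """
    by_id = {r.dye_id: r for r in results}
    series_by_id = {s.dye_id: s for s in series} if series else {}
    rows = []
    clusters = sorted({a.cluster_index for a in assignments})
    for c in clusters:
        members = [a for a in assignments if a.cluster_index == c]
        A_vals = np.array([a.A_value for a in members])
        stokes_vals: list[float] = []
        qy_vals: list[float] = []
        for a in members:
            s = series_by_id.get(a.dye_id)
            if s is None:
                continue
            for rec in s.records:
                stokes_vals.append(to_wavenumber_point(rec).stokes)
                if rec.quantum_yield is not None:
                    qy_vals.append(rec.quantum_yield)
        rows.append(
            {
                "cluster": c,
                "n_dyes": len(members),
                "A_min": A_vals.min(),
                "A_mean": A_vals.mean(),
                "A_max": A_vals.max(),
                "stokes_min_cm1": min(stokes_vals) if stokes_vals else np.nan,
                "stokes_max_cm1": max(stokes_vals) if stokes_vals else np.nan,
                "qy_min": min(qy_vals) if qy_vals else np.nan,
                "qy_max": max(qy_vals) if qy_vals else np.nan,
            }
        )
        _ = by_id  # results kept in signature for API symmetry/validation
    return pd.DataFrame(rows)


def assignments_to_frame(assignments: Sequence[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dye_id": a.dye_id,
                "k": a.k,
                "cluster": a.cluster_index,
                "A": a.A_value,
            }
            for a in assignments
        ]
    )
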