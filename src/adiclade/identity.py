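"""Pairwise identity matrices and their four summary statistics.

For an aligned set of nucleotide sequences the summary reports the mean
pairwise identity ā over all unordered pairs, its mean absolute deviation
ā_ad, and the largest and smallest pairwise identities a_max and a_min.
These four numbers, stratified within and between gene clusters, are the
descriptive backbone for calling homologue patterns from "very close"
orthologues down to "very distant" homologues.

Gap handling: the default ``pairwise_deletion`` scores matches over
columns where both rows carry a residue (gaps and N excluded per pair, the
same convention as the tree distances); ``count_gaps`` instead penalizes a
gap against a residue as a mismatch and skips only gap-vs-gap columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Default ā breakpoints separating the five homologue-pattern strata.
#: These numeric cut-offs are this package's own configuration — the
#: pattern vocabulary is standard, the thresholds are not.
DEFAULT_PATTERN_BREAKPOINTS: tuple[float, ...] = (0.95, 0.85, 0.70, 0.50)

PATTERN_LABELS: tuple[str, ...] = (
    "very close",
    "close",
    "typical",
    "distant",
    "very distant",
)


def pairwise_identity(
    row_i: str, row_j: str, gap_mode: str = "pairwise_deletion"
) -> float:
    """Proportion of identical residues between two aligned rows.

    Returns NaN when no comparable columns exist. N bases are excluded
    from both numerator and denominator in either mode.
    """
    if len(row_i) != len(row_j):
        raise ValueError(f"aligned rows differ in length: {len(row_i)} vs {len(row_j)}")
    if gap_mode not in ("pairwise_deletion", "count_gaps"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    matches = 0
    comparable = 0
    for a, b in zip(row_i, row_j):
        if a == "N" or b == "N":
            continue
        a_gap, b_gap = a == "-", b == "-"
        if a_gap and b_gap:
            continue
        if a_gap or b_gap:
            if gap_mode == "count_gaps":
                comparable += 1
            continue
        comparable += 1
        if a == b:
            matches += 1
    if comparable == 0:
        return math.nan
    return matches / comparable


def identity_matrix(
    rows: list[tuple[str, str]], gap_mode: str = "pairwise_deletion"
) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise identity matrix over aligned (id, row) pairs."""
    ids = [rid for rid, _ in rows]
    n = len(rows)
    m = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(rows[i][1], rows[j][1], gap_mode)
    return ids, m


@dataclass
class IdentitySummary:
    """Identity matrix with ā, ā_ad, a_max and a_min over all pairs."""

    ids: list[str]
    matrix: np.ndarray
    a_bar: float
    a_bar_ad: float
    a_max: float
    a_min: float

    def __str__(self) -> str:
        return (
            f"a_bar={self.a_bar:.3f} (a_max={self.a_max:.3f}, "
            f"a_min={self.a_min:.3f}, a_bar_ad={self.a_bar_ad:.3f})"
        )


def summarize(ids: list[str], matrix: np.ndarray) -> IdentitySummary:
    """Summary statistics over the n(n-1)/2 unordered off-diagonal pairs.

    Pairs with undefined identity (no comparable columns) are dropped from
    the statistics. Requires n >= 2 and at least one defined pair.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2 or len(ids) != n or matrix.shape != (n, n):
        raise ValueError("summarize needs a square matrix over >= 2 sequences")
    iu = np.triu_indices(n, k=1)
    pairs = matrix[iu]
    pairs = pairs[~np.isnan(pairs)]
    if pairs.size == 0:
        raise ValueError("no defined pairwise identities to summarize")
    a_bar = float(pairs.mean())
    return IdentitySummary(
        ids=list(ids),
        matrix=matrix,
        a_bar=a_bar,
        a_bar_ad=float(np.abs(pairs - a_bar).mean()),
        a_max=float(pairs.max()),
        a_min=float(pairs.min()),
    )


def summarize_alignment(
    rows: list[tuple[str, str]], gap_mode: str = "pairwise_deletion"
) -> IdentitySummary:
    ids, m = identity_matrix(rows, gap_mode)
    return summarize(ids, m)


def pattern_label(
    summary: IdentitySummary | float,
    breakpoints: tuple[float, ...] = DEFAULT_PATTERN_BREAKPOINTS,
) -> str:
    """Map ā into one of the five homologue-pattern strata.

    ``breakpoints`` must be strictly decreasing; ā at or above the k-th
    breakpoint gets the k-th label, anything below the last breakpoint is
    "very distant".
    """
    if list(breakpoints) != sorted(breakpoints, reverse=True) or len(
        set(breakpoints)
    ) != len(breakpoints):
        raise ValueError("breakpoints must be strictly decreasing")
    if len(breakpoints) != len(PATTERN_LABELS) - 1:
        raise ValueError(f"expected {len(PATTERN_LABELS) - 1} breakpoints")
    a_bar = summary.a_bar if isinstance(summary, IdentitySummary) else float(summary)
    for bp, label in zip(breakpoints, PATTERN_LABELS):
        if a_bar >= bp:
            return label
    return PATTERN_LABELS[-1]


def cluster_summaries(
    rows: list[tuple[str, str]],
    cluster_of: dict[str, str],
    gap_mode: str = "pairwise_deletion",
) -> dict[str, IdentitySummary]:
    """Per-cluster identity summaries (clusters with >= 2 members only)."""
    by_cluster: dict[str, list[tuple[str, str]]] = {}
    for rid, row in rows:
        by_cluster.setdefault(cluster_of[rid], []).append((rid, row))
    return {
        label: summarize_alignment(members, gap_mode)
        for label, members in sorted(by_cluster.items())
        if len(members) >= 2
    }
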