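"""Reliability testing of candidate coding sequences from read coverage.

A candidate CDS is called **complete** when every nucleotide has
consensus-agreeing read coverage, and **putative** otherwise; only
complete sequences enter the downstream analyses. "Consensus coverage"
means a base is supported only by read placements whose aligned base
matches the CDS base — mere overlap by a disagreeing read does not count.

Reads are placed by exact k-mer seeding on either strand followed by
ungapped full-length extension; a placement is kept when its mismatch
fraction does not exceed ``max_mismatch_frac``. This is deliberately
simple (Sanger-style verification of short CDS regions, no indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CodingRecord
from .simulate import SimulatedRead, reverse_complement

DEFAULT_MIN_SEED = 16
DEFAULT_MAX_MISMATCH_FRAC = 0.05
DEFAULT_MIN_SUPPORT = 1


@dataclass
class ReadPlacement:
    """One ungapped placement of a read on a CDS (forward coordinates)."""

    read_id: str
    start: int  # 1-based inclusive, CDS forward strand
    end: int  # 1-based inclusive
    mismatches: int
    strand: str  # "+" or "-"
    aligned_sequence: str  # read sequence in CDS forward orientation


@dataclass
class CoverageReport:
    """Per-base consensus support and the complete/putative verdict."""

    record_id: str
    per_base_support: np.ndarray
    uncovered: list[int]  # 1-based positions with support < min_support
    verdict: str  # "complete" | "putative"

    def uncovered_ranges(self) -> list[tuple[int, int]]:
        """Collapse uncovered positions into 1-based inclusive ranges."""
        ranges: list[tuple[int, int]] = []
        for pos in self.uncovered:
            if ranges and pos == ranges[-1][1] + 1:
                ranges[-1] = (ranges[-1][0], pos)
            else:
                ranges.append((pos, pos))
        return ranges


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def map_reads(
    cds: CodingRecord,
    reads: list[SimulatedRead],
    min_seed: int = DEFAULT_MIN_SEED,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[ReadPlacement]:
    """Place reads on a CDS by exact k-mer seeding and ungapped extension.

    Both strands are always searched; reverse placements are reported in
    forward CDS coordinates with the read reverse-complemented. For each
    read the placement with the fewest mismatches is kept (lowest start
    breaks ties), provided its mismatch fraction is within
    ``max_mismatch_frac``. Reads with no acceptable placement are dropped.
    """
    if not reads:
        return []
    if min_seed < 1:
        raise ValueError("min_seed must be >= 1")
    index = _kmer_index(cds.cds, min_seed)
    L = len(cds.cds)
    placements: list[ReadPlacement] = []
    for read in reads:
        if min_seed > len(read.sequence):
            continue
        best: tuple[int, int, str, str] | None = None  # (mismatches, start0, strand, oriented)
        for oriented, strand in (
            (read.sequence, "+"),
            (reverse_complement(read.sequence), "-"),
        ):
            rl = len(oriented)
            candidate_starts: set[int] = set()
            for off in range(rl - min_seed + 1):
                for hit in index.get(oriented[off : off + min_seed], ()):
                    start0 = hit - off
                    if 0 <= start0 and start0 + rl <= L:
                        candidate_starts.add(start0)
                if candidate_starts:
                    break  # first seeding k-mer with hits is enough
            for start0 in sorted(candidate_starts):
                ref = cds.cds[start0 : start0 + rl]
                mism = sum(1 for a, b in zip(oriented, ref) if a != b)
                key = (mism, start0, strand, oriented)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is None:
            continue
        mism, start0, strand, oriented = best
        if mism / len(oriented) <= max_mismatch_frac:
            placements.append(
                ReadPlacement(
                    read_id=read.read_id,
                    start=start0 + 1,
                    end=start0 + len(oriented),
                    mismatches=mism,
                    strand=strand,
                    aligned_sequence=oriented,
                )
            )
    placements.sort(key=lambda p: (p.start, p.read_id))
    return placements


def coverage_verdict(
    cds: CodingRecord,
    placements: list[ReadPlacement],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> CoverageReport:
    """Compute per-base consensus support and call complete/putative.

    A placement supports base i only where its aligned base agrees with
    the CDS base. The verdict is "complete" iff no position falls below
    ``min_support``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    L = len(cds.cds)
    support = np.zeros(L, dtype=int)
    for p in placements:
        ref = cds.cds[p.start - 1 : p.end]
        agree = np.frombuffer(p.aligned_sequence.encode(), dtype=np.uint8) == np.frombuffer(
            ref.encode(), dtype=np.uint8
        )
        support[p.start - 1 : p.end] += agree
    uncovered = (np.flatnonzero(support < min_support) + 1).tolist()
    return CoverageReport(
        record_id=cds.record_id,
        per_base_support=support,
        uncovered=uncovered,
        verdict="complete" if not uncovered else "putative",
    )


@dataclass
class ReliabilitySummary:
    """Batch verdicts over a set of candidate coding sequences."""

    n_complete: int
    n_putative: int
    reports: dict[str, CoverageReport] = field(default_factory=dict)

    @property
    def complete_ids(self) -> list[str]:
        return [rid for rid, rep in self.reports.items() if rep.verdict == "complete"]


def batch_reliability(
    candidates: list[CodingRecord],
    reads_by_record: dict[str, list[SimulatedRead]],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_seed: int = DEFAULT_MIN_SEED,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> ReliabilitySummary:
    """Run the reliability test over many candidates.

    Every candidate must have a read set in ``reads_by_record`` (an empty
    list is allowed and yields "putative" with all positions uncovered).
    Only "complete" records should be passed downstream.
    """
    missing = [c.record_id for c in candidates if c.record_id not in reads_by_record]
    if missing:
        raise ValueError(f"candidates without a read set: {missing}")
    reports: dict[str, CoverageReport] = {}
    for cand in candidates:
        placements = map_reads(
            cand, reads_by_record[cand.record_id], min_seed=min_seed,
            max_mismatch_frac=max_mismatch_frac,
        )
        reports[cand.record_id] = coverage_verdict(cand, placements, min_support=min_support)
    n_complete = sum(1 for r in reports.values() if r.verdict == "complete")
    return ReliabilitySummary(
        n_complete=n_complete, n_putative=len(reports) - n_complete, reports=reports
    )
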