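"""Protein primary-structure landmarks on alignments.

Annotates the landmark features used to compare major protein clusters:
cysteines shared by all rows (candidate disulphide positions),
N-glycosylation sequons N-{P}-[S/T] shared by all rows, exon-intron
splice-site positions mapped into alignment coordinates, and
collagen-like low-complexity regions of imperfect tandem tripeptide
repeats (G-x(2))_n. Signal-peptide cleavage positions are an external
annotation (e.g. from a prediction server) that is merely carried
through, never predicted here.

All reported columns and residue positions are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codon_align import CodonAlignment
from .records import CodingRecord

DEFAULT_COMMON_FRACTION = 1.0
DEFAULT_REPEAT_MAX_MISMATCH = 2
DEFAULT_REPEAT_MIN_N = 2


@dataclass
class TripeptideRepeat:
    """A maximal (G-x(2))_n run: 1-based start/end residues and n."""

    start: int
    end: int
    n: int


@dataclass
class LandmarkSet:
    """Landmark columns of one alignment (1-based alignment columns)."""

    common_cysteines: list[int] = field(default_factory=list)
    glyco_sites: list[int] = field(default_factory=list)
    splice_columns: dict[str, list[int]] = field(default_factory=dict)
    common_splice_columns: list[int] = field(default_factory=list)
    repeat_region: tuple[int, int, int] | None = None  # (start col, end col, n)
    signal_peptide_end: dict[str, int] = field(default_factory=dict)


def _rows(aln) -> list[tuple[str, str]]:
    if isinstance(aln, CodonAlignment):
        return list(zip(aln.record_ids, aln.protein_rows))
    return list(aln)


def find_common_cysteines(
    aln, min_fraction: float = DEFAULT_COMMON_FRACTION
) -> list[int]:
    """1-based columns where (by default all) rows have a cysteine.

    ``min_fraction`` relaxes "common" to a fraction of rows; gaps count
    against the fraction.
    """
    rows = _rows(aln)
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0][1])
    out = []
    for col in range(ncol):
        n_c = sum(1 for _, row in rows if row[col] == "C")
        if n_c / len(rows) >= min_fraction:
            out.append(col + 1)
    return out


def _sequon_at(ungapped: str, idx: int) -> bool:
    """N-{P}-[S/T] starting at 0-based residue idx of an ungapped row."""
    return (
        idx + 2 < len(ungapped)
        and ungapped[idx] == "N"
        and ungapped[idx + 1] != "P"
        and ungapped[idx + 2] in "ST"
    )


def find_common_glyco(
    aln, min_fraction: float = DEFAULT_COMMON_FRACTION
) -> list[int]:
    """1-based columns where every row begins an N-glycosylation sequon.

    The sequon is evaluated on each row's own ungapped local context (the
    two following residues of that sequence, wherever the alignment put
    them), so gapped columns between sequon positions do not break a
    site. Rows with a gap at the column count against the fraction.
    """
    rows = _rows(aln)
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0][1])
    ungapped = {rid: row.replace("-", "") for rid, row in rows}
    out = []
    for col in range(ncol):
        hits = 0
        for rid, row in rows:
            if row[col] == "-":
                continue
            idx = sum(1 for ch in row[:col] if ch != "-")
            if _sequon_at(ungapped[rid], idx):
                hits += 1
        if hits / len(rows) >= min_fraction:
            out.append(col + 1)
    return out


def find_tripeptide_repeats(
    row: str,
    min_n: int = DEFAULT_REPEAT_MIN_N,
    max_mismatch: int = DEFAULT_REPEAT_MAX_MISMATCH,
) -> TripeptideRepeat | None:
    """Longest imperfect (G-x(2))_n run in an ungapped protein sequence.

    Scans consecutive non-overlapping triplets in all three phases for
    the longest run whose first residues are G, allowing up to
    ``max_mismatch`` non-G triplets per run ("imperfect"); runs start and
    end on a G triplet. Returns 1-based inclusive residue coordinates and
    the triplet count n, the leftmost run on ties, or None when no run
    reaches ``min_n`` triplets.
    """
    if "-" in row:
        raise ValueError("find_tripeptide_repeats expects an ungapped row")
    best: TripeptideRepeat | None = None
    for phase in range(3):
        starts = range(phase, len(row) - 2, 3)
        is_g = [row[s] == "G" for s in starts]
        starts = list(starts)
        # two-pointer: longest window with <= max_mismatch non-G triplets
        lo = 0
        bad = 0
        for hi in range(len(is_g)):
            if not is_g[hi]:
                bad += 1
            while bad > max_mismatch:
                if not is_g[lo]:
                    bad -= 1
                lo += 1
            a, b = lo, hi
            while a <= b and not is_g[a]:  # trim to G at both ends
                a += 1
            while b >= a and not is_g[b]:
                b -= 1
            n = b - a + 1
            if n >= min_n:
                start = starts[a] + 1
                end = starts[b] + 3
                if best is None or n > best.n or (n == best.n and start < best.start):
                    best = TripeptideRepeat(start=start, end=end, n=n)
    return best


def map_splice_sites(record: CodingRecord, aln: CodonAlignment) -> list[int]:
    """Alignment columns of a record's internal exon-intron boundaries.

    Cumulative translated-exon lengths (nt) are converted to the codon
    containing each boundary's last exonic base (a boundary falling
    mid-codon is assigned to that codon), then mapped to 1-based
    alignment columns. A single-exon record has no internal boundaries.
    """
    if record.exon_lengths is None:
        raise ValueError(f"record {record.record_id!r} has no exon_lengths")
    cols = []
    cum = 0
    for exon_len in record.exon_lengths[:-1]:
        cum += exon_len
        codon_index0 = (cum - 1) // 3  # codon holding the last exonic base
        col0 = aln.column_of_residue(record.record_id, codon_index0)
        cols.append(col0 + 1)
    return cols


def annotate(
    aln: CodonAlignment,
    records: list[CodingRecord] | None = None,
    reference_id: str | None = None,
    min_fraction: float = DEFAULT_COMMON_FRACTION,
    repeat_min_n: int = DEFAULT_REPEAT_MIN_N,
    repeat_max_mismatch: int = DEFAULT_REPEAT_MAX_MISMATCH,
    signal_peptide_end: dict[str, int] | None = None,
) -> LandmarkSet:
    """Full landmark annotation of a codon alignment.

    Splice columns are reported per row and as the columns shared by all
    rows that have exon annotations (cross-species boundary jitter makes
    the per-row and intersected views both informative). The tripeptide
    repeat region is located on the reference row (the first row when
    ``reference_id`` is not given) and reported in alignment columns.
    """
    lm = LandmarkSet(
        common_cysteines=find_common_cysteines(aln, min_fraction),
        glyco_sites=find_common_glyco(aln, min_fraction),
        signal_peptide_end=dict(signal_peptide_end or {}),
    )
    if records:
        by_id = {r.record_id: r for r in records}
        per_row = {}
        for rid in aln.record_ids:
            rec = by_id.get(rid)
            if rec is not None and rec.exon_lengths is not None:
                per_row[rid] = map_splice_sites(rec, aln)
        lm.splice_columns = per_row
        if per_row:
            common = set.intersection(*(set(v) for v in per_row.values()))
            lm.common_splice_columns = sorted(common)
    ref = reference_id or aln.record_ids[0]
    ref_ungapped = aln.protein_rows[aln.row_index(ref)].replace("-", "")
    rep = find_tripeptide_repeats(ref_ungapped, repeat_min_n, repeat_max_mismatch)
    if rep is not None:
        start_col = aln.column_of_residue(ref, rep.start - 1) + 1
        end_col = aln.column_of_residue(ref, rep.end - 1) + 1
        lm.repeat_region = (start_col, end_col, rep.n)
    return lm
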