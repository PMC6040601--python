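"""Paired protein/nucleotide alignments (codon-aware threading).

Multiple protein alignment is an external input (any aligned FASTA, from
any aligner, possibly manually corrected). This module translates coding
sequences, threads the in-frame nucleotides onto a given protein alignment
— each residue becomes its source codon, each gap a ``---`` — and
validates that the two layers stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import STOP_CODONS, CodingRecord, translate_codon


class TranslationError(ValueError):
    pass


class ThreadingError(ValueError):
    pass


def translate(cds: CodingRecord | str, trim_terminal_stop: bool = True) -> str:
    """Translate an in-frame CDS with the standard genetic code.

    A trailing stop codon is dropped; an internal stop raises
    :class:`TranslationError` naming the offending codon index (1-based).
    Codons containing N translate to X.
    """
    seq = cds.cds if isinstance(cds, CodingRecord) else cds.upper()
    name = cds.record_id if isinstance(cds, CodingRecord) else "<sequence>"
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise TranslationError(f"{name}: CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if trim_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise TranslationError(
                f"{name}: internal stop codon {codon} at codon {i + 1} (1-based)"
            )
        out.append(translate_codon(codon))
    return "".join(out)


@dataclass
class CodonAlignment:
    """A protein alignment with its nucleotide layer threaded underneath.

    Invariants (checked by :meth:`validate`): all protein rows share one
    length; each nucleotide row is exactly 3x that long; ungapping a
    nucleotide row reproduces its source CDS; and translating each codon
    reproduces the protein row.
    """

    record_ids: list[str]
    protein_rows: list[str]
    nucleotide_rows: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.protein_rows[0]) if self.protein_rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.record_ids)

    def row_index(self, record_id: str) -> int:
        try:
            return self.record_ids.index(record_id)
        except ValueError:
            raise KeyError(f"record {record_id!r} not in alignment") from None

    def protein_column(self, col: int) -> list[str]:
        """Residues (or '-') at 0-based protein column ``col``."""
        return [row[col] for row in self.protein_rows]

    def codon_column(self, col: int) -> list[str]:
        """Codons (or '---') at 0-based protein column ``col``."""
        return [row[3 * col : 3 * col + 3] for row in self.nucleotide_rows]

    def column_of_residue(self, record_id: str, residue_index: int) -> int:
        """0-based alignment column holding this record's 0-based residue."""
        row = self.protein_rows[self.row_index(record_id)]
        seen = -1
        for col, ch in enumerate(row):
            if ch != "-":
                seen += 1
                if seen == residue_index:
                    return col
        raise IndexError(
            f"record {record_id!r} has only {seen + 1} residues; "
            f"residue index {residue_index} out of range"
        )

    def residue_of_column(self, record_id: str, col: int) -> int | None:
        """0-based ungapped residue index at column ``col``, or None on gap."""
        row = self.protein_rows[self.row_index(record_id)]
        if row[col] == "-":
            return None
        return sum(1 for ch in row[:col] if ch != "-")

    def ungapped_cds(self, record_id: str) -> str:
        return self.nucleotide_rows[self.row_index(record_id)].replace("-", "")

    def validate(self) -> "CodonAlignment":
        ncol = self.n_columns
        for rid, prow, nrow in zip(self.record_ids, self.protein_rows, self.nucleotide_rows):
            if len(prow) != ncol:
                raise ThreadingError(f"{rid}: protein row length {len(prow)} != {ncol}")
            if len(nrow) != 3 * ncol:
                raise ThreadingError(
                    f"{rid}: nucleotide row length {len(nrow)} != 3 x {ncol}"
                )
            for col in range(ncol):
                codon = nrow[3 * col : 3 * col + 3]
                if prow[col] == "-":
                    if codon != "---":
                        raise ThreadingError(
                            f"{rid}: column {col + 1}: protein gap over codon {codon}"
                        )
                elif (
                    "N" not in codon
                    and translate_codon(codon) != prow[col]
                    and prow[col] != "X"
                ):
                    raise ThreadingError(
                        f"{rid}: column {col + 1}: codon {codon} does not encode "
                        f"{prow[col]}"
                    )
        return self


def thread_nucleotides(
    protein_alignment: list[tuple[str, str]], cds_records: list[CodingRecord]
) -> CodonAlignment:
    """Thread in-frame CDS nucleotides onto a protein alignment.

    Every aligned row's ungapped residues must equal ``translate(cds)``
    for its record (terminal stop codons are trimmed before threading);
    the first disagreeing residue is reported otherwise.
    """
    by_id = {r.record_id: r for r in cds_records}
    rows = {rid: row.upper().replace(".", "-") for rid, row in protein_alignment}
    missing = [rid for rid in rows if rid not in by_id]
    if missing:
        raise ThreadingError(f"aligned rows without a CDS record: {missing}")
    record_ids, protein_rows, nucleotide_rows = [], [], []
    for rid, row in rows.items():
        rec = by_id[rid]
        aa = translate(rec)
        ungapped = row.replace("-", "")
        if len(ungapped) != len(aa):
            raise ThreadingError(
                f"{rid}: aligned row has {len(ungapped)} residues but the CDS "
                f"translates to {len(aa)}"
            )
        for i, (a, b) in enumerate(zip(ungapped, aa)):
            if a != b and a != "X" and b != "X":
                raise ThreadingError(
                    f"{rid}: residue {i + 1} (1-based) disagrees: alignment has "
                    f"{a}, translation has {b}"
                )
        codons = [rec.cds[i : i + 3] for i in range(0, 3 * len(aa), 3)]
        it = iter(codons)
        nuc_row = "".join("---" if ch == "-" else next(it) for ch in row)
        record_ids.append(rid)
        protein_rows.append(row)
        nucleotide_rows.append(nuc_row)
    return CodonAlignment(record_ids, protein_rows, nucleotide_rows).validate()
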