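"""Shared record model for coding sequences and gene families.

A :class:`CodingRecord` is one in-frame coding sequence (CDS) with its
species and gene-cluster labels; a :class:`GeneFamilySet` is the collection
of records the downstream statistics operate on, partitioned into major
gene clusters (orthologue groups).

Coordinates are 0-based half-open internally; every human-facing report
converts to 1-based inclusive and says so in its header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

#: Codon -> amino acid for the standard genetic code, stops excluded.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: Amino acid -> tuple of synonymous codons (standard code, no stops).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

VALID_NUCLEOTIDES = frozenset("ACGTN")


class FrameError(ValueError):
    """A CDS violates the in-frame coding-sequence invariants."""


def translate_codon(codon: str) -> str:
    """Translate one codon; codons containing N translate to 'X'."""
    if "N" in codon:
        return "X"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        if codon in STOP_CODONS:
            return "*"
        raise


@dataclass
class CodingRecord:
    """One coding sequence with its provenance labels.

    Parameters
    ----------
    record_id : str
        Unique identifier (an ENA accession for deposited data, or a
        synthetic id).
    species : str
        Source species; "unknown" when the input lacks it.
    cluster : str
        Major gene-cluster label (e.g. one of the controlled vocabulary
        ``ADIA``..``ADIR``, or a synthetic label). Free-form.
    cds : str
        In-frame nucleotide sequence over {A,C,G,T,N}. A terminal stop
        codon is accepted and trimmed with a logged note at validation.
    exon_lengths : list of int, optional
        Translated-exon lengths in nucleotides; must sum to ``len(cds)``.
    is_reference : bool
        Marks the reference sequence for site classification.
    """

    record_id: str
    species: str = "unknown"
    cluster: str = ""
    cds: str = ""
    exon_lengths: list[int] | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()

    def validate(self, trim_terminal_stop: bool = True) -> "CodingRecord":
        """Enforce the in-frame CDS invariants, returning self.

        Checks: alphabet {A,C,G,T,N}, length a positive multiple of 3, no
        internal stop codon, exon lengths (if any) summing to the CDS
        length. A stop codon at the very end is trimmed (with a log note)
        when ``trim_terminal_stop`` is true; internal stops are fatal.
        """
        bad = set(self.cds) - VALID_NUCLEOTIDES
        if bad:
            raise FrameError(
                f"record {self.record_id!r}: ambiguity codes other than N are "
                f"not supported: {sorted(bad)}"
            )
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise FrameError(
                f"record {self.record_id!r}: CDS length {len(self.cds)} is not "
                "a positive multiple of 3"
            )
        codons = self.codons()
        if trim_terminal_stop and codons and codons[-1] in STOP_CODONS:
            logger.info(
                "record %s: trimming terminal stop codon %s", self.record_id, codons[-1]
            )
            self.cds = self.cds[:-3]
            if self.exon_lengths:
                self.exon_lengths = list(self.exon_lengths)
                self.exon_lengths[-1] -= 3
                if self.exon_lengths[-1] <= 0:
                    raise FrameError(
                        f"record {self.record_id!r}: terminal exon shorter than "
                        "its stop codon"
                    )
            codons = self.codons()
        for i, codon in enumerate(codons):
            if codon in STOP_CODONS:
                raise FrameError(
                    f"record {self.record_id!r}: internal stop codon {codon} at "
                    f"codon index {i + 1} (1-based)"
                )
        if self.exon_lengths is not None:
            total = sum(self.exon_lengths)
            if any(e <= 0 for e in self.exon_lengths) or total != len(self.cds):
                raise FrameError(
                    f"record {self.record_id!r}: exon lengths {self.exon_lengths} "
                    f"do not sum to CDS length {len(self.cds)}"
                )
        return self

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass
class GeneFamilySet:
    """A set of coding records partitioned into major gene clusters."""

    records: list[CodingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")

    @property
    def clusters(self) -> dict[str, list[str]]:
        """Mapping cluster label -> record ids, in input order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.cluster, []).append(r.record_id)
        return out

    def by_id(self, record_id: str) -> CodingRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
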