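"""Protein molecular evolution test: RSCU and site classification.

Relative synonymous codon usage (RSCU, here ``R``) for a codon c of an
amino acid with k synonymous codons is the observed count of c divided by
its expected count under uniform usage within the family,
``R(c) = count(c) / (total(aa) / k)``. Codons with pooled ``R <= 0.7``
(over the whole coding-sequence set) form the **not-preferable** set.

Each residue of a chosen reference sequence is then classified from the
paired protein/nucleotide alignment:

* **invariant** — every row shows the same amino acid at the column (and,
  by default, no row has a gap there);
* **forward** — variant column whose observed codons include no
  not-preferable codon;
* **compensatory** — variant column whose observed codons include at
  least one not-preferable codon.

The idea: a variant site maintained through preferred codons suggests
straightforward substitution pressure, while involvement of rare codons
marks compensatory change.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import nan, isnan

from .codon_align import CodonAlignment
from .records import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    CodingRecord,
)

DEFAULT_R_THRESHOLD = 0.7

SITE_CLASSES = ("invariant", "forward", "compensatory")


def codon_usage(records: list[CodingRecord]) -> Counter:
    """Codon counts pooled over all records.

    Codons containing N are excluded; a terminal stop codon, if a record
    still carries one, is excluded too.
    """
    if not records:
        raise ValueError("codon_usage needs at least one record")
    counts: Counter = Counter()
    for rec in records:
        codons = rec.codons()
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for codon in codons:
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                raise ValueError(
                    f"record {rec.record_id!r} has an internal stop codon; "
                    "validate records first"
                )
            counts[codon] += 1
    return counts


@dataclass
class RSCUTable:
    """Observed counts, RSCU ratios and the not-preferable codon set.

    ``R`` maps every sense codon to its ratio (NaN when the amino acid
    was never observed). Within each synonymous family with nonzero total
    count the ratios sum to the family size k. Methionine and tryptophan
    (k = 1) always have R = 1 when observed and are never not-preferable
    in practice.
    """

    counts: Counter
    R: dict[str, float]
    threshold: float = DEFAULT_R_THRESHOLD
    not_preferable: set[str] = field(default_factory=set)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """R to report precision (2 decimals by default)."""
        return {
            c: (round(r, ndigits) if not isnan(r) else r) for c, r in self.R.items()
        }


def rscu(counts: Counter | dict, threshold: float = DEFAULT_R_THRESHOLD) -> RSCUTable:
    """RSCU table from pooled codon counts.

    ``not_preferable`` collects codons with ``R <= threshold`` (inclusive
    comparison). Codons of amino acids with zero total count get R = NaN
    and are never flagged.
    """
    counts = Counter(counts)
    if not counts:
        raise ValueError("rscu needs nonempty counts")
    bad = set(counts) - set(CODON_TO_AA)
    if bad:
        raise ValueError(f"not sense codons: {sorted(bad)}")
    R: dict[str, float] = {}
    not_pref: set[str] = set()
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            if total == 0:
                R[c] = nan
                continue
            R[c] = counts.get(c, 0) / (total / len(codons))
            if R[c] <= threshold:
                not_pref.add(c)
    return RSCUTable(counts=counts, R=R, threshold=threshold, not_preferable=not_pref)


@dataclass
class SiteRecord:
    """Classification evidence for one reference residue."""

    residue_index: int  # 1-based along the ungapped reference
    column: int  # 1-based alignment column
    reference_residue: str
    site_class: str
    residues_observed: set[str]
    codons_observed: set[str]
    has_gap: bool


@dataclass
class SiteClassification:
    """Per-residue classes along the reference sequence."""

    reference_id: str
    sites: list[SiteRecord]

    @property
    def n_invariant(self) -> int:
        return sum(1 for s in self.sites if s.site_class == "invariant")

    @property
    def n_forward(self) -> int:
        return sum(1 for s in self.sites if s.site_class == "forward")

    @property
    def n_compensatory(self) -> int:
        return sum(1 for s in self.sites if s.site_class == "compensatory")

    def by_class(self, site_class: str) -> list[SiteRecord]:
        return [s for s in self.sites if s.site_class == site_class]


def classify_sites(
    aln: CodonAlignment,
    reference_id: str,
    rscu_table: RSCUTable,
    gap_breaks_invariance: bool = True,
    column_codons: bool = True,
) -> SiteClassification:
    """Classify every reference residue as invariant/forward/compensatory.

    For each alignment column where the reference carries a residue: the
    site is invariant when all rows show that same amino acid (a gap in
    any row breaks invariance unless ``gap_breaks_invariance`` is off);
    otherwise it is compensatory when the codons observed at the column —
    in any row by default, or in the reference row only with
    ``column_codons=False`` — include a not-preferable codon, and forward
    otherwise. The three classes partition the reference residues.
    """
    ref_row = aln.protein_rows[aln.row_index(reference_id)]
    sites: list[SiteRecord] = []
    residue_index = 0
    for col, ref_res in enumerate(ref_row):
        if ref_res == "-":
            continue
        residue_index += 1
        residues = set(aln.protein_column(col))
        has_gap = "-" in residues
        residues_observed = residues - {"-"}
        codons = {c for c in aln.codon_column(col) if c != "---" and "N" not in c}
        invariant = len(residues_observed) == 1 and (
            not has_gap or not gap_breaks_invariance
        )
        if invariant:
            cls = "invariant"
        else:
            considered = (
                codons
                if column_codons
                else {aln.codon_column(col)[aln.row_index(reference_id)]}
            )
            cls = (
                "compensatory"
                if considered & rscu_table.not_preferable
                else "forward"
            )
        sites.append(
            SiteRecord(
                residue_index=residue_index,
                column=col + 1,
                reference_residue=ref_res,
                site_class=cls,
                residues_observed=residues_observed,
                codons_observed=codons,
                has_gap=has_gap,
            )
        )
    return SiteClassification(reference_id=reference_id, sites=sites)


def site_report(
    classification: SiteClassification,
    landmarks: "object | None" = None,
) -> tuple[list[tuple], dict]:
    """Per-site table rows and summary counts, cross-tabulated with landmarks.

    Returns (rows, summary). Rows are (residue index, alignment column,
    reference residue, class, observed residues, observed codons,
    landmark flags). ``landmarks`` is an optional LandmarkSet whose
    columns are matched against each site's alignment column. The summary
    includes counts per class plus landmark cross-tabs such as the number
    of invariant cysteines and invariant glycines inside the tripeptide
    repeat region.
    """
    lm_cys = set(getattr(landmarks, "common_cysteines", ()) or ())
    lm_glyco = set(getattr(landmarks, "glyco_sites", ()) or ())
    lm_splice = set(getattr(landmarks, "splice_columns", ()) or ())
    repeat = getattr(landmarks, "repeat_region", None)
    rows = []
    inv_cys = inv_gly_repeat = 0
    for s in classification.sites:
        flags = []
        if s.column in lm_cys:
            flags.append("cysteine")
        if s.column in lm_glyco:
            flags.append("glyco")
        if s.column in lm_splice:
            flags.append("splice")
        in_repeat = repeat is not None and repeat[0] <= s.column <= repeat[1]
        if in_repeat:
            flags.append("repeat")
        if s.site_class == "invariant":
            if s.column in lm_cys:
                inv_cys += 1
            if in_repeat and s.reference_residue == "G":
                inv_gly_repeat += 1
        rows.append(
            (
                s.residue_index,
                s.column,
                s.reference_residue,
                s.site_class,
                "".join(sorted(s.residues_observed)),
                ",".join(sorted(s.codons_observed)),
                ";".join(flags),
            )
        )
    summary = {
        "n_sites": len(classification.sites),
        "n_invariant": classification.n_invariant,
        "n_forward": classification.n_forward,
        "n_compensatory": classification.n_compensatory,
        "n_invariant_cysteines": inv_cys,
        "n_invariant_glycines_in_repeat": inv_gly_repeat,
    }
    return rows, summary
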