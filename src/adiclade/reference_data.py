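"""Published reference values for the deposited eutherian adiponectin set.

The curated third-party-data (TPA) gene data set of eutherian adiponectin
(*ADI*) genes is deposited in the European Nucleotide Archive under
accessions LT962964–LT963174 (211 complete coding sequences, 18 major
gene clusters ADIA–ADIR). The values below are the published analysis
results for that data set; `adiclade reproduce` recomputes the same
quantities from user-supplied copies of the records and prints a
side-by-side comparison. They are comparison references only — nothing in
this package derives results from them.
"""

from __future__ import annotations

ENA_ACCESSION_RANGE = ("LT962964", "LT963174")
N_COMPLETE_CDS = 211
N_POTENTIAL_CDS = 438  # pre-reliability candidate count; not reproducible offline
N_CLUSTERS = 18

#: Published pooled RSCU values (2 dp) for the 25 not-preferable codons
#: (R <= 0.7) of the deposited 211-CDS set.
NOT_PREFERABLE_R: dict[str, float] = {
    "TTT": 0.52, "TTA": 0.19, "TTG": 0.46, "CTT": 0.65, "CTA": 0.31,
    "ATA": 0.28, "GTT": 0.38, "GTA": 0.27, "TCA": 0.62, "TCG": 0.56,
    "CCG": 0.68, "ACG": 0.66, "GCA": 0.63, "GCG": 0.66, "TAT": 0.57,
    "CAT": 0.62, "CAA": 0.42, "AAT": 0.70, "AAA": 0.68, "GAT": 0.64,
    "GAA": 0.64, "TGT": 0.67, "CGT": 0.44, "AGT": 0.64, "GGT": 0.53,
}

#: Published identity summary of the full 211-homologue nucleotide alignment.
FULL_ALIGNMENT_IDENTITY = {
    "a_bar": 0.289,
    "a_max": 1.0,
    "a_min": 0.107,
    "a_bar_ad": 0.11,
}

#: Human ADIF1 vs ADIF2 coding-sequence identity (the differential
#: gene-expansion evidence).
ADIF1_ADIF2_IDENTITY = 0.99

#: Reference human ADIA protein: length and published site-class counts.
ADIA_REFERENCE = {
    "n_residues": 253,
    "n_invariant": 33,
    "n_forward": 1,
    "invariant_cysteines": ("C31", "C162", "C181"),
    "n_invariant_glycines_in_repeat": 21,
    "repeat_n": 26,
}

#: Human ADIR gene: single translated exon of 477 nt.
ADIR_CDS_LENGTH_NT = 477

#: Published grouping of the 18 major gene clusters into 5 groups on the
#: minimum-evolution tree.
CLUSTER_GROUPS: tuple[tuple[str, ...], ...] = (
    ("ADIA", "ADIB", "ADIC"),
    ("ADID", "ADIE", "ADIF", "ADIG", "ADIH"),
    ("ADII", "ADIJ", "ADIK", "ADIL"),
    ("ADIM",),
    ("ADIN", "ADIO", "ADIP", "ADIQ", "ADIR"),
)
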