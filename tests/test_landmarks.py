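"""Protein landmark annotation: cysteines, sequons, repeats, splice sites."""

import pytest

from adiclade.codon_align import thread_nucleotides
from adiclade.landmarks import (
    annotate,
    find_common_cysteines,
    find_common_glyco,
    find_tripeptide_repeats,
    map_splice_sites,
)
from adiclade.records import SYNONYMOUS_FAMILIES, CodingRecord


def cds_for(protein: str) -> str:
    return "".join(SYNONYMOUS_FAMILIES[aa][0] for aa in protein)


def aligned(rows):
    return [(f"r{i}", row) for i, row in enumerate(rows)]


class TestCommonCysteines:
    def test_single_row(self):
        assert find_common_cysteines(aligned(["ACA"])) == [2]

    def test_column_with_substitution_excluded(self):
        assert find_common_cysteines(aligned(["ACA", "ASA"])) == []

    def test_fraction_knob_relaxes_commonality(self):
        rows = aligned(["ACA", "ACA", "ASA"])
        assert find_common_cysteines(rows) == []
        assert find_common_cysteines(rows, min_fraction=0.6) == [2]

    def test_stable_under_row_reorder_and_duplication(self):
        rows = aligned(["CACGC", "CTCGC"])
        base = find_common_cysteines(rows)
        assert find_common_cysteines(list(reversed(rows))) == base
        assert find_common_cysteines(rows + [rows[0]]) == base


class TestCommonGlyco:
    def test_simple_sequon(self):
        assert find_common_glyco(aligned(["ANCSA"])) == [2]

    def test_proline_blocks_sequon(self):
        assert find_common_glyco(aligned(["ANPSA"])) == []

    def test_sequon_evaluated_on_ungapped_context(self):
        # the N's +1/+2 residues sit past a gap column in the alignment
        rows = [("a", "AN-CSA"), ("b", "ANQCTA")]
        assert 2 in find_common_glyco(rows, min_fraction=0.5)

    def test_planted_common_sequon_found_exactly(self, small_family,
                                                 small_alignment):
        cols = find_common_glyco(small_alignment)
        ncol = small_alignment.n_columns
        # verify against direct per-row check
        for col in cols:
            for rid in small_alignment.record_ids:
                row = small_alignment.protein_rows[small_alignment.row_index(rid)]
                ung = row.replace("-", "")
                idx = sum(1 for ch in row[: col - 1] if ch != "-")
                assert ung[idx] == "N" and ung[idx + 1] != "P" and ung[idx + 2] in "ST"
        assert all(1 <= c <= ncol for c in cols)


class TestTripeptideRepeats:
    def test_perfect_run(self):
        rep = find_tripeptide_repeats("GAAGBBGCC", max_mismatch=0)
        assert (rep.start, rep.end, rep.n) == (1, 9, 3)

    def test_imperfect_run_spans_mismatch_triplet(self):
        rep = find_tripeptide_repeats("GAAXAAGCCGDD", max_mismatch=1)
        assert (rep.start, rep.end, rep.n) == (1, 12, 4)

    def test_run_trimmed_to_g_triplets(self):
        rep = find_tripeptide_repeats("XAAGBBGCCXDD", max_mismatch=2)
        assert (rep.start, rep.end, rep.n) == (4, 9, 2)

    def test_below_min_n_returns_none(self):
        assert find_tripeptide_repeats("GAAKKK", min_n=2, max_mismatch=0) is None

    def test_leftmost_on_ties(self):
        rep = find_tripeptide_repeats("GAAGBBKKKKKKGCCGDD", max_mismatch=0)
        assert (rep.start, rep.n) == (1, 2)

    def test_off_phase_run_found(self):
        rep = find_tripeptide_repeats("K" + "GAA" * 5, max_mismatch=0)
        assert (rep.start, rep.end, rep.n) == (2, 16, 5)

    def test_collagen_like_region(self):
        # a (G-x-x)_26 collagen-like region inside a larger protein
        row = "MKLV" + "GPP" * 26 + "ACDEFH"
        rep = find_tripeptide_repeats(row)
        assert rep.n == 26
        assert (rep.start, rep.end) == (5, 4 + 78)


class TestSpliceSites:
    def test_single_exon_no_internal_boundaries(self):
        rec = CodingRecord("a", cds=cds_for("MKVA"), exon_lengths=[12]).validate()
        aln = thread_nucleotides([("a", "MKVA")], [rec])
        assert map_splice_sites(rec, aln) == []

    def test_boundary_on_codon_edge(self):
        # exons [300, 177] on a 477 nt CDS: boundary after codon 100
        protein = "M" * 159
        cds = cds_for(protein)
        rec = CodingRecord("a", cds=cds, exon_lengths=[300, 177]).validate()
        aln = thread_nucleotides([("a", protein)], [rec])
        assert map_splice_sites(rec, aln) == [100]

    def test_boundary_mid_codon_assigned_to_containing_codon(self):
        protein = "M" * 10
        rec = CodingRecord("a", cds=cds_for(protein), exon_lengths=[14, 16]).validate()
        aln = thread_nucleotides([("a", protein)], [rec])
        assert map_splice_sites(rec, aln) == [5]  # base 14 lies in codon 5

    def test_six_exons_give_five_splice_columns(self):
        protein = "M" * 60
        rec = CodingRecord("a", cds=cds_for(protein),
                           exon_lengths=[30, 30, 30, 30, 30, 30]).validate()
        aln = thread_nucleotides([("a", protein)], [rec])
        assert len(map_splice_sites(rec, aln)) == 5

    def test_missing_exon_lengths_is_error(self):
        rec = CodingRecord("a", cds=cds_for("MKVA")).validate()
        aln = thread_nucleotides([("a", "MKVA")], [rec])
        with pytest.raises(ValueError, match="exon_lengths"):
            map_splice_sites(rec, aln)


class TestAnnotate:
    def test_full_annotation_on_simulated_family(self, small_family,
                                                 small_alignment):
        fam, _ = small_family
        lm = annotate(small_alignment, fam.records)
        ncol = small_alignment.n_columns
        for col in lm.common_cysteines + lm.glyco_sites:
            assert 1 <= col <= ncol
        if lm.repeat_region:
            start, end, n = lm.repeat_region
            assert 1 <= start <= end <= ncol and n >= 2

    def test_signal_peptide_passthrough(self, small_family, small_alignment):
        fam, _ = small_family
        ends = {fam.records[0].record_id: 20}
        lm = annotate(small_alignment, fam.records, signal_peptide_end=ends)
        assert lm.signal_peptide_end == ends
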