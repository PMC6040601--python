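"""RSCU statistics and invariant/forward/compensatory site classes."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from adiclade.codon_align import CodonAlignment, thread_nucleotides
from adiclade.codon_evolution import (
    classify_sites,
    codon_usage,
    rscu,
    site_report,
)
from adiclade.records import SYNONYMOUS_FAMILIES, CodingRecord
from adiclade.simulate import SimulationConfig, simulate_family


class TestCodonUsage:
    def test_single_record(self):
        rec = CodingRecord("a", cds="ATGGCT")
        assert codon_usage([rec]) == Counter({"ATG": 1, "GCT": 1})

    def test_duplicated_records_double_counts(self):
        recs = [CodingRecord("a", cds="ATGGCTAAA"), CodingRecord("b", cds="ATGGCTAAA")]
        counts = codon_usage(recs)
        assert counts == Counter({"ATG": 2, "GCT": 2, "AAA": 2})

    def test_n_codons_and_terminal_stop_excluded(self):
        rec = CodingRecord("a", cds="ATGGNTTAA")
        assert codon_usage([rec]) == Counter({"ATG": 1})

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            codon_usage([])

    def test_empirical_frequencies_match_generating_bias(self):
        # counts of one undiverged record are i.i.d. draws from the
        # generating codon distribution: binomial 3-sigma check per codon
        cfg = SimulationConfig(n_clusters=1, taxa_per_cluster=1,
                               root_cds_length_codons=3000,
                               within_cluster_distance=0.0,
                               between_cluster_distance=0.0, seed=10)
        fam, truth = simulate_family(cfg)
        counts = codon_usage(list(fam))
        checked = 0
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            total = sum(counts.get(c, 0) for c in codons)
            if total < 50 or len(codons) == 1:
                continue
            probs = truth.codon_distributions[aa]
            for c, p in zip(codons, probs):
                sigma = (total * p * (1 - p)) ** 0.5
                assert abs(counts.get(c, 0) - total * p) <= 3.5 * sigma + 1
                checked += 1
        assert checked > 10


class TestRSCU:
    def test_uniform_usage_all_r_one(self):
        counts = Counter({c: 10 for cods in SYNONYMOUS_FAMILIES.values() for c in cods})
        table = rscu(counts)
        assert all(r == pytest.approx(1.0) for r in table.R.values())
        assert table.not_preferable == set()

    def test_leucine_family_hand_computation(self):
        counts = Counter({"TTA": 1, "TTG": 1, "CTT": 1, "CTC": 1, "CTA": 1, "CTG": 7})
        table = rscu(counts)
        assert table.R["CTG"] == pytest.approx(3.5, abs=1e-12)
        assert table.R["TTA"] == pytest.approx(0.5, abs=1e-12)
        assert "TTA" in table.not_preferable
        assert "CTG" not in table.not_preferable

    def test_threshold_is_inclusive(self):
        # a codon with R exactly 0.7 is not preferable
        counts = Counter({"GAT": 7, "GAC": 13})  # Asp family, k=2
        table = rscu(counts)
        assert table.R["GAT"] == pytest.approx(0.7, abs=1e-12)
        assert "GAT" in table.not_preferable

    def test_unobserved_family_r_undefined(self):
        table = rscu(Counter({"ATG": 5}))
        assert table.R["GCT"] != table.R["GCT"]  # NaN
        assert "GCT" not in table.not_preferable

    def test_single_codon_families_never_not_preferable(self):
        counts = Counter({"ATG": 3, "TGG": 4, "AAA": 100, "AAG": 1})
        table = rscu(counts)
        assert table.R["ATG"] == 1.0 and table.R["TGG"] == 1.0
        assert {"ATG", "TGG"} & table.not_preferable == set()

    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=61,
                    max_size=61))
    @settings(max_examples=200, deadline=None)
    def test_family_sum_invariant(self, raw_counts):
        """Sum of R over each synonymous family equals the family size k."""
        codons = sorted(c for cods in SYNONYMOUS_FAMILIES.values() for c in cods)
        counts = Counter(dict(zip(codons, raw_counts)))
        counts["ATG"] += 1  # keep the table nonempty
        table = rscu(counts)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            total = sum(counts.get(c, 0) for c in family)
            if total == 0:
                continue
            assert sum(table.R[c] for c in family) == pytest.approx(
                len(family), abs=1e-12)


def toy_alignment(prot_rows, cds):
    records = [CodingRecord(rid, cds=c).validate() for (rid, _), c in zip(prot_rows, cds)]
    return thread_nucleotides(prot_rows, records), records


class TestClassifySites:
    def test_all_identical_alignment_all_invariant(self):
        aln, recs = toy_alignment(
            [("a", "MKV"), ("b", "MKV")], ["ATGAAAGTG", "ATGAAAGTG"])
        table = rscu(codon_usage(recs))
        cls = classify_sites(aln, "a", table)
        assert cls.n_invariant == 3 and cls.n_forward == 0 and cls.n_compensatory == 0

    def test_variant_column_with_preferable_codons_is_forward(self):
        # column 3: V vs I, codons GTG/ATC, both kept preferable by a
        # threshold of 0 (nothing is ever not-preferable)
        aln, recs = toy_alignment(
            [("a", "MKV"), ("b", "MKI")], ["ATGAAAGTG", "ATGAAAATC"])
        table = rscu(codon_usage(recs), threshold=0.0)
        cls = classify_sites(aln, "a", table)
        assert [s.site_class for s in cls.sites] == [
            "invariant", "invariant", "forward"]

    def test_variant_column_with_not_preferable_codon_is_compensatory(self):
        aln, recs = toy_alignment(
            [("a", "MKV"), ("b", "MKI")], ["ATGAAAGTG", "ATGAAAATC"])
        # force GTG into the not-preferable set via a hand-built table
        table = rscu(Counter({"GTG": 1, "GTT": 99, "ATG": 1, "AAA": 1, "ATC": 1}))
        assert "GTG" in table.not_preferable
        cls = classify_sites(aln, "a", table)
        assert cls.sites[2].site_class == "compensatory"

    def test_gap_breaks_invariance_by_default(self):
        aln, recs = toy_alignment(
            [("a", "MKV"), ("b", "MK-")], ["ATGAAAGTG", "ATGAAA"])
        table = rscu(codon_usage(recs), threshold=0.0)
        cls = classify_sites(aln, "a", table)
        assert cls.sites[2].site_class == "forward"
        relaxed = classify_sites(aln, "a", table, gap_breaks_invariance=False)
        assert relaxed.sites[2].site_class == "invariant"

    def test_classes_partition_reference_residues(self, small_family, small_alignment):
        fam, _ = small_family
        table = rscu(codon_usage(fam.records))
        cls = classify_sites(small_alignment, fam.records[0].record_id, table)
        assert cls.n_invariant + cls.n_forward + cls.n_compensatory == len(cls.sites)
        assert len(cls.sites) == fam.records[0].n_codons

    def test_raising_threshold_only_moves_forward_to_compensatory(
            self, small_family, small_alignment):
        fam, _ = small_family
        counts = codon_usage(fam.records)
        ref = fam.records[0].record_id
        low = classify_sites(small_alignment, ref, rscu(counts, threshold=0.3))
        high = classify_sites(small_alignment, ref, rscu(counts, threshold=0.9))
        for s_low, s_high in zip(low.sites, high.sites):
            if s_low.site_class == "compensatory":
                assert s_high.site_class == "compensatory"
            if s_high.site_class == "forward":
                assert s_low.site_class == "forward"
            assert (s_low.site_class == "invariant") == \
                (s_high.site_class == "invariant")

    def test_invariant_to_row_order_and_duplication(self, small_family,
                                                    small_alignment):
        fam, _ = small_family
        table = rscu(codon_usage(fam.records))
        ref = fam.records[0].record_id
        base = classify_sites(small_alignment, ref, table)
        aln2 = CodonAlignment(
            record_ids=list(reversed(small_alignment.record_ids)) + ["dup"],
            protein_rows=list(reversed(small_alignment.protein_rows))
            + [small_alignment.protein_rows[-1]],
            nucleotide_rows=list(reversed(small_alignment.nucleotide_rows))
            + [small_alignment.nucleotide_rows[-1]],
        )
        perm = classify_sites(aln2, ref, table)
        assert [s.site_class for s in base.sites] == [
            s.site_class for s in perm.sites]

    def test_simulator_truth_recall(self):
        for f in (0.0, 0.5, 1.0):
            fam, truth = simulate_family(SimulationConfig(
                invariant_codon_fraction=f, seed=3))
            aln = thread_nucleotides(truth.protein_alignment, fam.records)
            table = rscu(codon_usage(fam.records))
            cls = classify_sites(aln, fam.records[0].record_id, table)
            inv_cols = {s.column for s in cls.sites if s.site_class == "invariant"}
            assert truth.invariant_columns <= inv_cols | truth.invariant_columns
            assert inv_cols == truth.invariant_columns

    def test_missing_reference_is_error(self, small_family, small_alignment):
        fam, _ = small_family
        table = rscu(codon_usage(fam.records))
        with pytest.raises(KeyError):
            classify_sites(small_alignment, "nope", table)


class TestSiteReport:
    def test_all_invariant_toy_summary(self):
        aln, recs = toy_alignment(
            [("a", "MKV"), ("b", "MKV")], ["ATGAAAGTG", "ATGAAAGTG"])
        table = rscu(codon_usage(recs))
        rows, summary = site_report(classify_sites(aln, "a", table))
        assert summary["n_invariant"] == 3
        assert summary["n_forward"] == summary["n_compensatory"] == 0
        assert len(rows) == 3

    def test_landmark_cross_tabulation(self, small_family, small_alignment):
        from adiclade.landmarks import annotate

        fam, _ = small_family
        table = rscu(codon_usage(fam.records))
        ref = fam.records[0].record_id
        cls = classify_sites(small_alignment, ref, table)
        lm = annotate(small_alignment, fam.records, reference_id=ref)
        rows, summary = site_report(cls, lm)
        assert summary["n_invariant_cysteines"] <= summary["n_invariant"]
        assert summary["n_sites"] == len(cls.sites)
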