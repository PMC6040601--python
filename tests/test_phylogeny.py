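"""Distances, NJ/OLS/NNI minimum-evolution search, bootstrap, monophyly."""

import math

import dendropy
import numpy as np
import pytest

from _oracles import (
    exhaustive_me_minimum,
    random_additive_matrix,
)
from adiclade.phylogeny import (
    DistanceMatrix,
    SaturationError,
    bootstrap,
    canonical_split,
    cluster_groups,
    distances,
    me_tree,
    neighbor_joining,
    ols_branch_lengths,
)
from adiclade.simulate import SimulationConfig, simulate_family


def rf_distance(newick_a: str, newick_b: str) -> int:
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)


class TestDistances:
    def test_identical_rows_zero(self):
        rows = [("a", "ACGTACGTACGT"), ("b", "ACGTACGTACGT"), ("c", "ACGTACGTACGT")]
        for model in ("p", "JC", "TN93_pooled"):
            dm = distances(rows, model=model)
            assert np.allclose(dm.d, 0.0)

    def test_jc_closed_form(self):
        rows = [("a", "ACGT"), ("b", "ACGA")]
        dm_p = distances(rows, model="p")
        assert dm_p.d[0, 1] == pytest.approx(0.25)
        dm_jc = distances(rows, model="JC")
        assert dm_jc.d[0, 1] == pytest.approx(-0.75 * math.log(2.0 / 3.0), abs=1e-9)

    def test_jc_saturation_flagged_not_capped(self):
        rows = [("a", "AAAA"), ("b", "CCCC")]
        dm = distances(rows, model="JC")
        assert ("a", "b") in dm.saturated
        assert math.isnan(dm.d[0, 1])
        with pytest.raises(SaturationError):
            dm.require_finite()

    def test_pairwise_deletion_excludes_gap_columns(self):
        rows = [("a", "ACGT--GT"), ("b", "ACGAACGT"), ("c", "ACGTACGT")]
        dm = distances(rows, model="p")
        assert dm.d[0, 1] == pytest.approx(1.0 / 6.0)

    @pytest.mark.parametrize("d_true", [0.05, 0.15, 0.30])
    def test_tn93_pooled_recovers_true_distance(self, d_true):
        # parameter recovery: two sequences separated by a known distance
        # under an equal-rate process (mismatch prob 3/4(1 - e^{-4d/3})),
        # ensemble mean of the estimate within 10% of truth
        n_sites = 5000
        p_mismatch = 0.75 * (1.0 - math.exp(-4.0 * d_true / 3.0))
        estimates = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            a = rng.choice(list("ACGT"), size=n_sites)
            b = a.copy()
            flip = rng.random(n_sites) < p_mismatch
            for i in np.flatnonzero(flip):
                b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
            rows = [("a", "".join(a)), ("b", "".join(b))]
            dm = distances(rows, model="TN93_pooled")
            assert dm.d[0, 1] >= distances(rows, model="p").d[0, 1]
            estimates.append(dm.d[0, 1])
        assert np.mean(estimates) == pytest.approx(d_true, rel=0.10)


class TestMETree:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(list("abc"), d, "p")
        tree = me_tree(dm, search="nj_only")
        lengths = sorted(tree.branch_lengths.values())
        la = 0.5 * (0.3 + 0.5 - 0.6)
        lb = 0.5 * (0.3 + 0.6 - 0.5)
        lc = 0.5 * (0.5 + 0.6 - 0.3)
        assert lengths == pytest.approx(sorted([la, lb, lc]), abs=1e-12)

    def test_five_taxon_additive_exact_recovery(self):
        rng = np.random.default_rng(5)
        dm, true_tree = random_additive_matrix(5, rng)
        tree = me_tree(dm, search="nj_plus_nni")
        assert tree.internal_splits() == true_tree.internal_splits()
        # branch lengths recovered exactly (additive-metric identity)
        est = ols_branch_lengths(tree, dm)
        for e, l in est.items():
            assert l == pytest.approx(
                true_tree.raw_lengths[_match_edge(tree, true_tree, e)], abs=1e-9)

    def test_nj_additive_exactness_up_to_ten_taxa(self):
        # NJ alone reconstructs the generating topology from additive input
        for n in (4, 6, 8, 10):
            rng = np.random.default_rng(n)
            dm, true_tree = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            assert tree.internal_splits() == true_tree.internal_splits()

    def test_nj_matches_independent_implementation(self):
        # cross-check against scikit-bio's neighbor joining
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(33)
        dm, _ = random_additive_matrix(8, rng)
        ours = me_tree(dm, search="nj_only")
        sk_tree = skbio_nj(SkbioDM(dm.d, ids=dm.ids))
        assert rf_distance(ours.newick(), str(sk_tree)) == 0

    def test_nni_never_increases_me_criterion(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.uniform(0.1, 1.0, (7, 7))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix([f"t{i}" for i in range(7)], d, "p")
            start = neighbor_joining(dm)
            start.raw_lengths = ols_branch_lengths(start, dm)
            final = me_tree(dm, search="nj_plus_nni")
            assert final.raw_total_length <= start.raw_total_length + 1e-10

    def test_nni_reaches_exhaustive_minimum_mostly(self):
        # small version of the all-topology oracle comparison
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            d = rng.uniform(0.1, 1.0, (6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix([f"t{i}" for i in range(6)], d, "p")
            best = exhaustive_me_minimum(dm)
            got = me_tree(dm, search="nj_plus_nni").raw_total_length
            assert got >= best - 1e-9
            hits += abs(got - best) < 1e-9
        assert hits >= 18

    def test_saturated_matrix_refused(self):
        d = np.array([[0.0, np.nan, 0.2], [np.nan, 0.0, 0.2], [0.2, 0.2, 0.0]])
        dm = DistanceMatrix(list("abc"), d, "JC", saturated=[("a", "b")])
        with pytest.raises(SaturationError, match="a-b"):
            me_tree(dm)


def _match_edge(tree, true_tree, edge):
    """Find true_tree's edge inducing the same bipartition as tree's edge."""
    target = tree.split_of_edge(edge)
    for e in true_tree.edges():
        if true_tree.split_of_edge(e) == target:
            return e
    raise AssertionError("no matching edge")


class TestBootstrap:
    def test_single_replicate_supports_zero_or_hundred(self, small_family):
        _, truth = small_family
        tree = bootstrap(truth.nucleotide_alignment, model="p", replicates=1, seed=3,
                         search="nj_only")
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_true_clusters_strongly_supported(self, small_family):
        _, truth = small_family
        tree = bootstrap(truth.nucleotide_alignment, model="TN93_pooled",
                         replicates=100, seed=9)
        all_taxa = frozenset(t for t, _ in truth.cluster_assignment.items())
        for label in set(truth.cluster_assignment.values()):
            mem = frozenset(k for k, v in truth.cluster_assignment.items()
                            if v == label)
            split = canonical_split(mem, all_taxa)
            assert tree.supports[split] >= 90

    def test_structureless_columns_weakly_supported(self):
        # permuting residues within each row destroys shared signal
        rng = np.random.default_rng(0)
        rows = [(f"t{i}", "".join(rng.choice(list("ACGT"), 300))) for i in range(8)]
        tree = bootstrap(rows, model="p", replicates=50, seed=4, search="nj_only")
        assert np.mean(list(tree.supports.values())) < 50

    def test_fixed_seed_reproducible_and_leaf_order_invariant(self, small_family):
        _, truth = small_family
        rows = truth.nucleotide_alignment
        t1 = bootstrap(rows, replicates=30, seed=8, search="nj_only")
        t2 = bootstrap(rows, replicates=30, seed=8, search="nj_only")
        assert t1.supports == t2.supports


class TestClusterGroups:
    def test_clean_family_all_monophyletic(self, small_family, small_alignment):
        _, truth = small_family
        tree = me_tree(distances(small_alignment))
        report = cluster_groups(tree, truth.cluster_assignment)
        assert report.all_monophyletic

    def test_mislabeled_leaf_breaks_monophyly(self, small_family, small_alignment):
        _, truth = small_family
        tree = me_tree(distances(small_alignment))
        wrong = dict(truth.cluster_assignment)
        a_leaf = next(k for k, v in wrong.items() if v == "CLA")
        wrong[a_leaf] = "CLB"
        report = cluster_groups(tree, wrong)
        assert not report.monophyletic["CLA"]
        assert not report.monophyletic["CLB"]

    def test_unlabeled_leaf_is_error(self, small_family, small_alignment):
        _, truth = small_family
        tree = me_tree(distances(small_alignment))
        partial = dict(truth.cluster_assignment)
        partial.pop(next(iter(partial)))
        with pytest.raises(ValueError, match="without a cluster label"):
            cluster_groups(tree, partial)

    def test_me_tree_recovers_true_cluster_structure(self):
        fam, truth = simulate_family(SimulationConfig(
            n_clusters=3, taxa_per_cluster=5, within_cluster_distance=0.05,
            between_cluster_distance=1.0, seed=42))
        tree = me_tree(distances(truth.nucleotide_alignment))
        report = cluster_groups(tree, truth.cluster_assignment)
        assert report.all_monophyletic
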