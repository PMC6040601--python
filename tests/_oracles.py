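"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: topology enumeration
by stepwise addition, brute-force pair loops, and four-point-condition
additive matrices built directly from known trees.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from adiclade.phylogeny import DistanceMatrix, PhyloTree, ols_branch_lengths


def all_unrooted_topologies(n: int) -> list[PhyloTree]:
    """Every unrooted binary topology over n labelled leaves (stepwise
    addition: (2n-5)!! trees, 105 for n = 6)."""
    taxa = [str(i) for i in range(n)]
    trees = [({0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}, n + 1)]
    for leaf in range(3, n):
        grown = []
        for adj, nxt in trees:
            t = PhyloTree(taxa, adj)
            for e in t.edges():
                u, v = sorted(e)
                a = {k: set(s) for k, s in adj.items()}
                a[u].discard(v)
                a[v].discard(u)
                a[u].add(nxt)
                a[v].add(nxt)
                a[nxt] = {u, v, leaf}
                a[leaf] = {nxt}
                grown.append((a, nxt + 1))
        trees = grown
    return [PhyloTree(taxa, a) for a, _ in trees]


def exhaustive_me_minimum(dm: DistanceMatrix) -> float:
    """Global minimum-evolution score: min over all topologies of the
    total OLS branch length."""
    return min(
        sum(ols_branch_lengths(t, dm).values())
        for t in all_unrooted_topologies(len(dm.ids))
    )


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, PhyloTree]:
    """Additive distance matrix from a random binary tree with strictly
    positive branch lengths, plus the generating tree."""
    taxa = [str(i) for i in range(n)]
    adj: dict[int, set[int]] = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    nxt = n + 1
    for leaf in range(3, n):
        tree = PhyloTree(taxa, adj)
        edges = tree.edges()
        u, v = sorted(edges[rng.integers(len(edges))])
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(nxt)
        adj[v].add(nxt)
        adj[nxt] = {u, v, leaf}
        adj[leaf] = {nxt}
        nxt += 1
    tree = PhyloTree(taxa, adj)
    tree.raw_lengths = {e: float(rng.uniform(0.05, 0.5)) for e in tree.edges()}
    # leaf-to-leaf path lengths
    d = np.zeros((n, n))
    paths = tree._leaf_paths()
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = sum(tree.raw_lengths[e] for e in paths[i][j])
    return DistanceMatrix(taxa, d, "p"), tree


def brute_force_identity_summary(matrix: np.ndarray) -> tuple[float, float, float, float]:
    """(a_bar, a_bar_ad, a_max, a_min) via an explicit double loop."""
    n = matrix.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(matrix[i, j]):
                pairs.append(matrix[i, j])
    a_bar = sum(pairs) / len(pairs)
    a_ad = sum(abs(p - a_bar) for p in pairs) / len(pairs)
    return a_bar, a_ad, max(pairs), min(pairs)
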