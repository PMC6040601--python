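"""Distance-based minimum-evolution phylogenetics.

Pipeline: pairwise distances from the nucleotide layer of a codon-aware
alignment (p-distance, Jukes-Cantor, or a pooled-parameter Tamura-Nei
1993 variant approximating composite-likelihood distances), a
neighbor-joining starting topology, ordinary-least-squares (OLS) branch
lengths on the fixed topology, and optional nearest-neighbor-interchange
(NNI) descent on the minimum-evolution criterion (total OLS tree length
S). Bootstrap support resamples codon columns (blocks of three
nucleotide columns, preserving frame) and reports the percentage of
replicate trees containing each internal bipartition.

Gap treatment is pairwise deletion throughout: for each sequence pair,
columns where either sequence has a gap or N are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np

MODELS = ("p", "JC", "TN93_pooled")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distances undefined for some pairs (too divergent for the model)."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        super().__init__(
            "distance undefined (saturated) for pairs: "
            + ", ".join(f"{a}-{b}" for a, b in pairs)
        )


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with the model that produced it.

    Saturated pairs (model formula undefined) are stored as NaN and
    listed in ``saturated`` rather than silently capped; tree search
    refuses to run on them.
    """

    ids: list[str]
    d: np.ndarray
    model: str
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def require_finite(self) -> None:
        if self.saturated or not np.all(np.isfinite(self.d)):
            raise SaturationError(self.saturated)


def _rows_from_alignment(aln) -> list[tuple[str, str]]:
    if hasattr(aln, "nucleotide_rows"):  # CodonAlignment
        return list(zip(aln.record_ids, aln.nucleotide_rows))
    return list(aln)


def _pair_counts(a: str, b: str) -> tuple[int, int, int, int]:
    """(comparable sites, matches, transitions, transversions) under
    pairwise deletion (gap or N in either row excludes the column)."""
    n = match = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            match += 1
        elif (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, match, ts, tv


def distances(aln, model: str = "TN93_pooled", gap_mode: str = "pairwise_deletion") -> DistanceMatrix:
    """Pairwise distances from aligned nucleotide rows.

    ``aln`` is a CodonAlignment (its nucleotide layer is used) or a list
    of (id, aligned sequence) pairs; at least 3 rows are required for
    downstream tree building but 2 are accepted here.

    Models: ``p`` (mismatch proportion), ``JC`` (Jukes-Cantor,
    saturating at p >= 3/4) and ``TN93_pooled`` — the Tamura-Nei 1993
    formula evaluated with base frequencies pooled over all sequences
    once, then applied per pair with that pair's transition and
    transversion proportions (a composite-likelihood-style approximation
    to MEGA's maximum composite likelihood distances).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if gap_mode != "pairwise_deletion":
        raise ValueError("only pairwise_deletion gap treatment is supported")
    rows = _rows_from_alignment(aln)
    ids = [rid for rid, _ in rows]
    seqs = [s.upper() for _, s in rows]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")

    if model == "TN93_pooled":
        counts = {b: 0 for b in "ACGT"}
        for s in seqs:
            for b in "ACGT":
                counts[b] += s.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no unambiguous bases in alignment")
        gA, gC, gG, gT = (counts[b] / total for b in "ACGT")
        gR, gY = gA + gG, gC + gT
        k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
        k2 = 2.0 * gT * gC / gY if gY > 0 else 0.0
        k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
                    - (gT * gC * gR / gY if gY > 0 else 0.0))

    d = np.zeros((n, n), dtype=float)
    saturated: list[tuple[str, str]] = []
    for i, j in combinations(range(n), 2):
        sites, match, ts, tv = _pair_counts(seqs[i], seqs[j])
        if sites == 0:
            d[i, j] = d[j, i] = np.nan
            saturated.append((ids[i], ids[j]))
            continue
        p = (sites - match) / sites
        if model == "p":
            val = p
        elif model == "JC":
            if p >= 0.75:
                val = np.nan
            else:
                val = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        else:  # TN93_pooled
            # split transitions into purine (A<->G) and pyrimidine (C<->T)
            ts1 = sum(
                1
                for x, y in zip(seqs[i], seqs[j])
                if x != y and x in _PURINES and y in _PURINES
            )
            P1 = ts1 / sites
            P2 = (ts - ts1) / sites
            Q = tv / sites
            w1 = 1.0 - (P1 / k1 if k1 > 0 else 0.0) - Q / (2.0 * gR)
            w2 = 1.0 - (P2 / k2 if k2 > 0 else 0.0) - Q / (2.0 * gY)
            w3 = 1.0 - Q / (2.0 * gR * gY)
            if min(w1, w2, w3) <= 0.0:
                val = np.nan
            else:
                val = -(k1 * np.log(w1) + k2 * np.log(w2) + k3 * np.log(w3))
        if np.isnan(val):
            saturated.append((ids[i], ids[j]))
        d[i, j] = d[j, i] = val
    return DistanceMatrix(ids=ids, d=d, model=model, saturated=saturated)


# ---------------------------------------------------------------------------
# tree structure


class PhyloTree:
    """Unrooted tree with OLS branch lengths and optional supports.

    Nodes are integers; leaves 0..n-1 carry taxon names. Branch lengths
    are kept twice: ``raw_lengths`` are the unconstrained OLS estimates
    (used by the ME criterion) and ``branch_lengths`` the display values
    with negatives clamped to zero. ``supports`` maps canonical leaf-name
    bipartitions to bootstrap percentages.
    """

    def __init__(self, taxa: list[str], adjacency: dict[int, set[int]]):
        self.taxa = list(taxa)
        self.adjacency = {u: set(vs) for u, vs in adjacency.items()}
        self.raw_lengths: dict[frozenset, float] = {}
        self.supports: dict[frozenset, float] = {}

    # -- basic structure ---------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def edges(self) -> list[frozenset]:
        return sorted(
            {frozenset((u, v)) for u, vs in self.adjacency.items() for v in vs},
            key=sorted,
        )

    def internal_edges(self) -> list[frozenset]:
        n = self.n_leaves
        return [e for e in self.edges() if all(x >= n for x in e)]

    @property
    def branch_lengths(self) -> dict[frozenset, float]:
        return {e: max(0.0, l) for e, l in self.raw_lengths.items()}

    @property
    def total_length(self) -> float:
        """ME criterion S: total tree length over displayed branch lengths."""
        return sum(self.branch_lengths.values())

    @property
    def raw_total_length(self) -> float:
        return sum(self.raw_lengths.values())

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.taxa, self.adjacency)
        t.raw_lengths = dict(self.raw_lengths)
        t.supports = dict(self.supports)
        return t

    # -- bipartitions ------------------------------------------------------

    def _side_leaves(self, u: int, v: int) -> frozenset:
        """Leaves reachable from v when edge (u, v) is cut."""
        seen = {u, v}
        stack = [v]
        leaves = set()
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                leaves.add(self.taxa[x])
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(leaves)

    def split_of_edge(self, edge: frozenset) -> frozenset:
        u, v = sorted(edge)
        return canonical_split(self._side_leaves(u, v), frozenset(self.taxa))

    def internal_splits(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (one per internal edge)."""
        return {self.split_of_edge(e) for e in self.internal_edges()}

    # -- OLS machinery -----------------------------------------------------

    def _leaf_paths(self) -> dict[int, dict[int, list[frozenset]]]:
        """For each leaf, edge path to every other node (BFS)."""
        paths: dict[int, dict[int, list[frozenset]]] = {}
        for leaf in range(self.n_leaves):
            prev: dict[int, int] = {leaf: leaf}
            order = [leaf]
            for x in order:
                for y in self.adjacency[x]:
                    if y not in prev:
                        prev[y] = x
                        order.append(y)
            p: dict[int, list[frozenset]] = {}
            for node in order:
                if node == leaf:
                    p[node] = []
                else:
                    p[node] = p[prev[node]] + [frozenset((prev[node], node))]
            paths[leaf] = p
        return paths

    def to_dendropy(self, use_raw: bool = False, clamp: bool = True) -> dendropy.Tree:
        ns = dendropy.TaxonNamespace(self.taxa)
        tree = dendropy.Tree(taxon_namespace=ns)
        lengths = self.raw_lengths if use_raw else self.branch_lengths
        n = self.n_leaves
        # root at an internal node (or a leaf's neighbor for n <= 2)
        root_id = next((x for x in self.adjacency if x >= n), 0)
        nodes: dict[int, dendropy.Node] = {root_id: tree.seed_node}
        stack = [root_id]
        seen = {root_id}
        while stack:
            u = stack.pop()
            for v in self.adjacency[u]:
                if v in seen:
                    continue
                seen.add(v)
                child = dendropy.Node()
                child.edge.length = lengths.get(frozenset((u, v)), None)
                if clamp and child.edge.length is not None:
                    child.edge.length = max(0.0, child.edge.length)
                if v < n:
                    child.taxon = ns.get_taxon(self.taxa[v])
                else:
                    split = self.split_of_edge(frozenset((u, v)))
                    if split in self.supports:
                        child.label = f"{self.supports[split]:g}"
                nodes[v] = child
                nodes[u].add_child(child)
                stack.append(v)
        return tree

    def newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
            real_value_format_specifier=".6f",
        ).strip()


def canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not holding min(taxa)."""
    ref = min(all_taxa)
    return frozenset(all_taxa - side) if ref in side else frozenset(side)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ; ties in the Q criterion break to the lowest-index pair.

    Branch lengths produced here are provisional; callers refit them by
    OLS. Requires n >= 3 (n = 3 yields the unique unrooted topology).
    """
    dm.require_finite()
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = {i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    active = list(range(n))
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    next_id = n

    def link(u: int, v: int) -> None:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i][j] - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        u = next_id
        next_id += 1
        link(u, i)
        link(u, j)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
            D.setdefault(u, {})[k] = duk
            D[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    center = next_id
    for k in active:
        link(center, k)
    return PhyloTree(dm.ids, adjacency)


# ---------------------------------------------------------------------------
# OLS branch lengths and minimum-evolution search


def ols_branch_lengths(tree: PhyloTree, dm: DistanceMatrix) -> dict[frozenset, float]:
    """Unconstrained OLS branch-length estimates on a fixed topology.

    Solves the dense least-squares system whose design matrix indicates,
    for every unordered leaf pair, which edges lie on its path. Exact on
    additive matrices.
    """
    dm.require_finite()
    edges = tree.edges()
    edge_index = {e: k for k, e in enumerate(edges)}
    n = tree.n_leaves
    paths = tree._leaf_paths()
    pairs = list(combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.empty(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in paths[i][j]:
            A[row, edge_index[e]] = 1.0
        y[row] = dm.d[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {e: float(x[k]) for e, k in edge_index.items()}


def _nni_neighbors(tree: PhyloTree, edge: frozenset):
    """The two NNI rearrangements across an internal edge."""
    u, v = sorted(edge)
    a, b = sorted(tree.adjacency[u] - {v})[:2]
    c, d = sorted(tree.adjacency[v] - {u})[:2]
    for swap_u, swap_v in ((b, c), (b, d)):
        t = tree.copy()
        t.adjacency[u].discard(swap_u)
        t.adjacency[swap_u].discard(u)
        t.adjacency[v].discard(swap_v)
        t.adjacency[swap_v].discard(v)
        t.adjacency[u].add(swap_v)
        t.adjacency[swap_v].add(u)
        t.adjacency[v].add(swap_u)
        t.adjacency[swap_u].add(v)
        t.raw_lengths = {}
        yield t


def me_tree(dm: DistanceMatrix, search: str = "nj_plus_nni") -> PhyloTree:
    """Minimum-evolution tree: NJ start, OLS lengths, optional NNI descent.

    With ``nj_plus_nni``, any nearest-neighbor interchange lowering the
    total OLS tree length is accepted (best improvement per sweep) until
    no interchange improves it — a monotone descent on the ME criterion.
    Negative OLS branch lengths are clamped to zero in displayed output;
    raw estimates are retained on the tree.
    """
    if search not in ("nj_only", "nj_plus_nni"):
        raise ValueError(f"unknown search {search!r}")
    tree = neighbor_joining(dm)
    tree.raw_lengths = ols_branch_lengths(tree, dm)
    if search == "nj_only" or tree.n_leaves < 4:
        return tree
    current_s = tree.raw_total_length
    improved = True
    while improved:
        improved = False
        best: tuple[float, PhyloTree] | None = None
        for edge in tree.internal_edges():
            for cand in _nni_neighbors(tree, edge):
                cand.raw_lengths = ols_branch_lengths(cand, dm)
                s = cand.raw_total_length
                if s < current_s - 1e-10 and (best is None or s < best[0]):
                    best = (s, cand)
        if best is not None:
            current_s, tree = best
            improved = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(
    aln,
    model: str = "TN93_pooled",
    replicates: int = 100,
    seed: int = 0,
    search: str = "nj_plus_nni",
) -> PhyloTree:
    """ME tree with bootstrap supports from codon-column resampling.

    Columns are resampled in blocks of three nucleotide columns so
    replicates stay in frame. Supports are the percentage of successful
    replicates whose tree contains each internal bipartition of the tree
    estimated from the full alignment; the conventional 50% reporting
    threshold is a display choice, not applied here. Replicates whose
    distances saturate are skipped (counted out of the denominator).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = _rows_from_alignment(aln)
    length = len(rows[0][1])
    if length % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3 (codon columns)")
    n_blocks = length // 3
    main = me_tree(distances(rows, model=model), search=search)
    splits = {s: 0 for s in main.internal_splits()}
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(replicates):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        rep_rows = [
            (rid, "".join(s[3 * b : 3 * b + 3] for b in pick)) for rid, s in rows
        ]
        try:
            rep_tree = me_tree(distances(rep_rows, model=model), search=search)
        except (SaturationError, ValueError):
            continue
        n_ok += 1
        rep_splits = rep_tree.internal_splits()
        for s in splits:
            if s in rep_splits:
                splits[s] += 1
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed (saturated distances)")
    main.supports = {s: 100.0 * c / n_ok for s, c in splits.items()}
    return main


# ---------------------------------------------------------------------------
# cluster monophyly


@dataclass
class MonophylyReport:
    """Monophyly of each labelled cluster plus the between-cluster grouping."""

    monophyletic: dict[str, bool]
    cluster_splits: list[frozenset]  # splits expressible as unions of clusters

    @property
    def all_monophyletic(self) -> bool:
        return all(self.monophyletic.values())


def cluster_groups(tree: PhyloTree, cluster_map: dict[str, str]) -> MonophylyReport:
    """Test each cluster for monophyly on an unrooted tree.

    A cluster is monophyletic when some edge bipartition separates
    exactly its leaves (trivially true for singleton clusters and for a
    cluster covering all leaves). ``cluster_splits`` lists the internal
    bipartitions whose sides are unions of complete clusters — the
    grouping obtained by collapsing each cluster to a single leaf.
    """
    unlabeled = [t for t in tree.taxa if t not in cluster_map]
    if unlabeled:
        raise ValueError(f"leaves without a cluster label: {unlabeled}")
    all_taxa = frozenset(tree.taxa)
    members: dict[str, set[str]] = {}
    for leaf in tree.taxa:
        members.setdefault(cluster_map[leaf], set()).add(leaf)
    edge_splits = set()
    for e in tree.edges():
        edge_splits.add(tree.split_of_edge(e))
    monophyletic = {}
    for label, mem in members.items():
        if len(mem) in (1, len(all_taxa)):
            monophyletic[label] = True
        else:
            monophyletic[label] = canonical_split(frozenset(mem), all_taxa) in edge_splits
    cluster_splits = []
    for s in sorted(tree.internal_splits(), key=lambda s: (len(s), sorted(s))):
        for side in (set(s), set(all_taxa - s)):
            labels = {cluster_map[t] for t in side}
            if all(members[l] <= side for l in labels):
                cluster_splits.append(frozenset(labels))
                break
    return MonophylyReport(monophyletic=monophyletic, cluster_splits=cluster_splits)
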