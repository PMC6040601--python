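"""Synthetic gene-family generator.

Generates multi-cluster coding-sequence families with the statistical
structure the downstream analyses assume — orthologue clusters whose
within-cluster identity far exceeds between-cluster identity, a
controllable fraction of invariant codon columns, biased synonymous codon
usage (so a non-trivial set of rare codons with RSCU ``R <= 0.7`` exists),
codon-multiple deletions, and simulated read sets with engineered per-base
coverage gaps — together with exact truth tables, so every analysis stage
is verifiable without downloading data.

Model summary (see docs/methods.md for the full account):

* The guide tree is a star of cluster ancestors, each at half the
  between-cluster distance from the root, with a random ultrametric
  within-cluster tree of height half the within-cluster distance.
* Sequences evolve by codon-level resampling: the number of substitution
  events per codon on a branch of length ``t`` substitutions/site is
  Poisson(3t); an event is synonymous (codon resampled from the family's
  biased codon distribution) or, at non-invariant columns only,
  nonsynonymous (new amino acid, codon drawn from the bias).
* Designated invariant columns never change amino acid and are never
  deleted; designated non-invariant columns are guaranteed to show
  amino-acid variation among the leaves (a post-pass substitutes one
  lineage if drift left a column uniform), so the truth table is exact.
* Indels are codon-multiple deletions at non-invariant columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    CODON_TO_AA,
    SYNONYMOUS_FAMILIES,
    CodingRecord,
    GeneFamilySet,
)

AMINO_ACIDS = tuple(sorted(SYNONYMOUS_FAMILIES))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of the gene-family simulation.

    Distances are in substitutions/site. Defaults emulate a small version
    of the strata seen in real eutherian gene families: tight orthologue
    clusters (within-cluster distance 0.05, i.e. "very close" identities)
    separated by deep divergence (between-cluster distance 1.0, "distant"
    to "very distant" identities).
    """

    n_clusters: int = 3
    taxa_per_cluster: int = 5
    root_cds_length_codons: int = 120
    within_cluster_distance: float = 0.05
    between_cluster_distance: float = 1.0
    invariant_codon_fraction: float = 0.25
    codon_bias_strength: float = 1.5
    indel_rate: float = 0.0  # deletion events per codon per unit branch length
    nonsyn_fraction: float = 0.5  # fraction of events that change the amino acid
    guarantee_variation: bool = True  # force >= 2 amino acids at non-invariant columns
    append_stop: bool = False
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_clusters < 1 or self.taxa_per_cluster < 1:
            raise ValueError("n_clusters and taxa_per_cluster must be >= 1")
        if self.root_cds_length_codons < 1:
            raise ValueError("root_cds_length_codons must be >= 1")
        if not (0.0 <= self.invariant_codon_fraction <= 1.0):
            raise ValueError("invariant_codon_fraction must lie in [0, 1]")
        if self.n_clusters > 1 and not (
            self.between_cluster_distance > self.within_cluster_distance
        ):
            raise ValueError(
                "between_cluster_distance must exceed within_cluster_distance"
            )
        if min(self.within_cluster_distance, self.between_cluster_distance,
               self.codon_bias_strength, self.indel_rate) < 0:
            raise ValueError("distances, bias strength and indel rate must be >= 0")
        return self


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated family."""

    true_tree: str  # newick with branch lengths, leaf names = record ids
    invariant_columns: set[int]  # 1-based codon-column indices (root coords)
    cluster_assignment: dict[str, str]  # record id -> cluster label
    per_base_coverage: dict[str, np.ndarray] = field(default_factory=dict)
    protein_alignment: list[tuple[str, str]] = field(default_factory=list)
    nucleotide_alignment: list[tuple[str, str]] = field(default_factory=list)
    codon_distributions: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# internal tree scaffolding for the simulation


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[_Node] = []
        self.length = length

    def newick(self) -> str:
        def fmt(node: _Node) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _random_ultrametric(names: list[str], height: float, rng: np.random.Generator) -> _Node:
    """Random ultrametric tree over ``names`` with root-to-tip ``height``.

    Built by coalescing random pairs at increasing node heights (sorted
    uniforms scaled to ``height``), a cheap stand-in for a Yule tree.
    """
    nodes = [(_Node(name=n), 0.0) for n in names]
    if len(nodes) == 1:
        node, _ = nodes[0]
        node.length = height
        return node
    merge_heights = np.sort(rng.uniform(0.0, 1.0, size=len(names) - 1)) * height
    if len(names) >= 2:  # force the last merge at the root height
        merge_heights[-1] = height
    for h in merge_heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = h - ha
        b.length = h - hb
        parent = _Node()
        parent.children = [a, b]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, h))
    root, _ = nodes[0]
    return root


# ---------------------------------------------------------------------------
# codon machinery


def biased_codon_distributions(
    strength: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities with tunable usage bias.

    For a synonymous family of k codons, weights are ``exp(-strength * r)``
    over a random permutation of ranks r = 0..k-1. ``strength = 0`` gives
    uniform usage (all RSCU = 1); larger values concentrate usage on a few
    preferred codons, leaving rare codons with R well below 0.7.
    """
    dists: dict[str, np.ndarray] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        k = len(codons)
        ranks = rng.permutation(k)
        w = np.exp(-strength * ranks.astype(float))
        dists[aa] = w / w.sum()
    return dists


def _draw_codon(aa: str, dists: dict[str, np.ndarray], rng: np.random.Generator) -> str:
    codons = SYNONYMOUS_FAMILIES[aa]
    return codons[rng.choice(len(codons), p=dists[aa])]


# ---------------------------------------------------------------------------
# family simulation


def simulate_family(config: SimulationConfig) -> tuple[GeneFamilySet, SimulationTruth]:
    """Simulate one gene family; deterministic for a fixed seed.

    Returns the family (ungapped in-frame CDS per record, one cluster
    label per record) and the exact truth: the generating tree, the set of
    invariant codon columns, cluster assignments, and the true protein and
    nucleotide alignments in root coordinates.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_bias, rng_root, rng_tree, rng_evo, rng_fix = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    L = config.root_cds_length_codons
    dists = biased_codon_distributions(config.codon_bias_strength, rng_bias)

    root_aas = [AMINO_ACIDS[rng_root.integers(len(AMINO_ACIDS))] for _ in range(L)]
    root_codons = [_draw_codon(aa, dists, rng_root) for aa in root_aas]

    n_inv = int(round(config.invariant_codon_fraction * L))
    invariant = set(rng_root.choice(L, size=n_inv, replace=False).tolist())

    # guide tree: star of cluster ancestors + ultrametric cluster trees
    root = _Node()
    cluster_labels = [f"CL{chr(ord('A') + i)}" for i in range(config.n_clusters)]
    cluster_assignment: dict[str, str] = {}
    for ci, label in enumerate(cluster_labels):
        names = [f"{label}_t{j + 1}" for j in range(config.taxa_per_cluster)]
        for n in names:
            cluster_assignment[n] = label
        sub = _random_ultrametric(names, config.within_cluster_distance / 2.0, rng_tree)
        sub.length += config.between_cluster_distance / 2.0
        root.children.append(sub)

    # evolve codons down the tree; a genome is (codons, deleted-column set)
    leaves: dict[str, tuple[list[str], set[int]]] = {}

    def evolve(node: _Node, codons: list[str], deleted: set[int]) -> None:
        codons = list(codons)
        deleted = set(deleted)
        t = node.length
        if t > 0:
            for col in range(L):
                if col in deleted:
                    continue
                n_events = rng_evo.poisson(3.0 * t)
                for _ in range(n_events):
                    aa = CODON_TO_AA[codons[col]]
                    if col not in invariant and rng_evo.random() < config.nonsyn_fraction:
                        choices = [a for a in AMINO_ACIDS if a != aa]
                        aa = choices[rng_evo.integers(len(choices))]
                    codons[col] = _draw_codon(aa, dists, rng_evo)
            if config.indel_rate > 0:
                n_del = rng_evo.poisson(config.indel_rate * t * L)
                candidates = [c for c in range(L) if c not in deleted and c not in invariant]
                for _ in range(min(n_del, len(candidates))):
                    pick = candidates.pop(rng_evo.integers(len(candidates)))
                    deleted.add(pick)
        if node.children:
            for child in node.children:
                evolve(child, codons, deleted)
        else:
            leaves[node.name] = (codons, deleted)

    evolve(root, root_codons, set())

    # guarantee realized variation at every non-invariant column
    leaf_names = list(cluster_assignment)
    for col in range(L):
        if col in invariant or not config.guarantee_variation:
            continue
        observed = {
            CODON_TO_AA[leaves[n][0][col]] for n in leaf_names if col not in leaves[n][1]
        }
        holders = [n for n in leaf_names if col not in leaves[n][1]]
        if len(observed) == 1 and holders:
            name = holders[rng_fix.integers(len(holders))]
            aa = observed.pop()
            choices = [a for a in AMINO_ACIDS if a != aa]
            new_aa = choices[rng_fix.integers(len(choices))]
            leaves[name][0][col] = _draw_codon(new_aa, dists, rng_fix)

    records: list[CodingRecord] = []
    prot_aln: list[tuple[str, str]] = []
    nuc_aln: list[tuple[str, str]] = []
    for i, name in enumerate(leaf_names):
        codons, deleted = leaves[name]
        kept = [codons[c] for c in range(L) if c not in deleted]
        rec = CodingRecord(
            record_id=name,
            species=f"species_{i + 1}",
            cluster=cluster_assignment[name],
            cds="".join(kept),
            is_reference=(i == 0),
        ).validate()
        if config.append_stop:
            rec.cds += "TAA"
        records.append(rec)
        prot_row = "".join(
            "-" if c in deleted else CODON_TO_AA[codons[c]] for c in range(L)
        )
        nuc_row = "".join("---" if c in deleted else codons[c] for c in range(L))
        prot_aln.append((name, prot_row))
        nuc_aln.append((name, nuc_row))

    truth = SimulationTruth(
        true_tree=root.newick(),
        invariant_columns={c + 1 for c in invariant},
        cluster_assignment=cluster_assignment,
        protein_alignment=prot_aln,
        nucleotide_alignment=nuc_aln,
        codon_distributions=dists,
    )
    return GeneFamilySet(records=records), truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedRead:
    """One simulated sequencing read with its true placement."""

    read_id: str
    sequence: str
    start: int  # 1-based position of the read's first base on the CDS
    strand: str  # "+" or "-"

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + len(self.sequence) - 1


def simulate_reads(
    record: CodingRecord,
    depth: float = 10.0,
    read_length: int = 50,
    dropout_intervals: list[tuple[int, int]] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate ungapped reads from a CDS with engineered coverage gaps.

    No read overlaps a dropout interval (1-based inclusive ranges), which
    engineers per-base coverage exactly zero there. Outside dropouts the
    expected coverage equals ``depth``: each contiguous allowed segment at
    least one read long is first tiled end to end (so nonzero-error-free
    coverage is guaranteed), then random uniformly placed reads top the
    coverage up. Reads come from both strands; substitution errors are
    i.i.d. per base at ``error_rate``.
    """
    dropout_intervals = dropout_intervals or []
    L = len(record.cds)
    if read_length > L:
        raise ValueError(f"read_length {read_length} exceeds CDS length {L}")
    if read_length < 1 or depth < 0:
        raise ValueError("read_length must be >= 1 and depth >= 0")
    for a, b in dropout_intervals:
        if not (1 <= a <= b <= L):
            raise ValueError(f"dropout interval ({a}, {b}) outside [1, {L}]")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD0)))
    blocked = np.zeros(L, dtype=bool)
    for a, b in dropout_intervals:
        blocked[a - 1 : b] = True

    # allowed start positions (0-based): read must avoid every blocked base
    window_blocked = np.convolve(blocked.astype(int), np.ones(read_length, dtype=int))[
        read_length - 1 : L
    ]
    allowed_starts = np.flatnonzero(window_blocked == 0)

    starts: list[int] = []
    # tile each contiguous run of allowed starts: start-anchored step
    # read_length, plus the end-anchored read, covering the whole segment
    if allowed_starts.size:
        breaks = np.flatnonzero(np.diff(allowed_starts) > 1)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)), np.concatenate((breaks, [allowed_starts.size - 1]))
        )
        for lo, hi in run_bounds:
            first, last = int(allowed_starts[lo]), int(allowed_starts[hi])
            starts.extend(range(first, last + 1, read_length))
            starts.append(last)
        n_random = max(0, int(round((depth - 1.0) * allowed_starts.size / read_length)))
        if n_random:
            starts.extend(rng.choice(allowed_starts, size=n_random).tolist())

    reads: list[SimulatedRead] = []
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    for i, s in enumerate(starts):
        frag = record.cds[s : s + read_length]
        if error_rate > 0:
            arr = np.array(list(frag))
            hit = rng.random(len(arr)) < error_rate
            for j in np.flatnonzero(hit):
                alternatives = [b for b in bases if b != arr[j]]
                arr[j] = alternatives[rng.integers(len(alternatives))]
            frag = "".join(arr)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = frag if strand == "+" else reverse_complement(frag)
        reads.append(
            SimulatedRead(
                read_id=f"{record.record_id}_r{i + 1}",
                sequence=seq,
                start=s + 1,
                strand=strand,
            )
        )
    return reads


def write_reads_fastq(reads: list[SimulatedRead], path) -> None:
    """Write simulated reads as FASTQ (constant quality 'I')."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_reads(path) -> list[SimulatedRead]:
    """Read FASTA/FASTQ reads back as :class:`SimulatedRead` (placement unknown)."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if open(path).read(1) == "@" else "fasta"
    return [
        SimulatedRead(read_id=rec.id, sequence=str(rec.seq).upper(), start=0, strand="?")
        for rec in SeqIO.parse(path, fmt)
    ]


def expected_coverage(reads: list[SimulatedRead], cds_length: int) -> np.ndarray:
    """Raw per-base read coverage (overlap counting, no consensus check)."""
    cov = np.zeros(cds_length, dtype=int)
    for r in reads:
        if r.start >= 1:
            cov[r.start - 1 : r.end] += 1
    return cov
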