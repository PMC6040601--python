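# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the design decisions taken where the protocol left the
choice open.

## Coordinates and record model

Internally all coordinates are 0-based half-open; every human-facing
report uses 1-based inclusive positions and says so in its header. A
coding record is an in-frame CDS over {A,C,G,T,N}: length a positive
multiple of 3, no internal stop codon (standard genetic code), optional
translated-exon lengths summing to the CDS length. A terminal stop codon
is accepted and trimmed with a logged note; ambiguity codes other than N
are rejected at parse time, and codons containing N are excluded from
all codon counting. Cluster labels are free-form; the 18-label
vocabulary ADIA–ADIR of the deposited adiponectin set ships as
documentation, not as a constraint.

## Reliability testing

The test asks whether archival sequencing reads independently confirm
every base of a candidate CDS. Reads are placed by exact k-mer seeding
(default seed length 16) on both strands, extended ungapped over the
full read, and kept when the mismatch fraction is ≤ 0.05; per read the
fewest-mismatch placement wins, lowest start on ties. *Consensus
coverage* is deliberately strict: a base is supported only by placements
whose aligned base equals the CDS base, so a position where all reads
disagree with the candidate has support 0 even though reads overlap it.
The verdict is *complete* iff every position reaches `min_support`
(default 1). These defaults are explicit, configurable interpretations —
the protocol's description fixes the complete/putative rule but not a
minimum read count or a mismatch policy. Ungapped extension is a
deliberate restriction (Sanger-style verification of short regions);
indel-tolerant mapping is out of scope.

The verdict is monotone in reads (adding reads never flips complete →
putative), which the suite tests directly.

## Codon-aware alignments

Multiple protein alignment is an external input: any aligned FASTA, from
any aligner, possibly hand-corrected. Threading replaces each residue by
its source codon and each gap by `---`, after trimming terminal stops
and verifying that the ungapped row equals the CDS translation (first
disagreeing residue reported). Two invariants are enforced and
property-tested: ungapping a nucleotide row reproduces the CDS
bit-exactly, and nucleotide columns are always exactly 3× protein
columns.

## Identity statistics

Identity is the fraction of matching residues among comparable columns.
Default gap handling is pairwise deletion (columns with a gap in either
row skipped), matching the distance treatment used for trees; a
`count_gaps` mode (gap-vs-residue counts as mismatch, gap-vs-gap
skipped) is retained because alignment editors often penalize gaps, and
the reproduction harness can try both. N is excluded from numerator and
denominator in both modes. Summaries are over the n(n−1)/2 unordered
pairs; pairs with no comparable columns are reported missing and dropped
from summaries.

The five homologue-pattern strata (very close / close / typical /
distant / very distant) are thresholded on ā at 0.95/0.85/0.70/0.50.
These breakpoints are this package's configuration: the pattern
vocabulary is standard but no numeric cut-offs were published.

## Distances and minimum-evolution trees

Three distance models are provided: p-distance, Jukes–Cantor
(saturating at p ≥ 3/4), and `TN93_pooled` — the Tamura–Nei (1993)
formula evaluated with base frequencies pooled once over all sequences
and each pair's own transition (purine and pyrimidine separately) and
transversion proportions. The pooled variant is this package's
documented approximation to "maximum composite likelihood" distances as
popularized by MEGA, whose exact iteration is underdocumented; pooling
the frequency parameters captures the composite character while staying
testable (the suite verifies 10% parameter recovery on sequences
simulated under a known equal-rate process). Saturated pairs are flagged
and stored as NaN, never silently capped; tree search refuses to run on
them and names the offending pairs.

Tree estimation follows the classical minimum-evolution recipe:
neighbor joining for the starting topology (ties in the Q criterion
break to the lowest-index pair, for determinism), ordinary-least-squares
branch lengths on the fixed topology (dense least squares over the
path-incidence system; exact on additive matrices), then
nearest-neighbor-interchange descent accepting the best
length-reducing move per sweep until no move lowers the total OLS
length S. Negative OLS branch lengths are clamped to zero in displayed
output only; the raw estimates drive the ME criterion and remain
available. On 100 random 6-taxon matrices the search attains the
exhaustive 105-topology minimum in ≥ 95 cases (measured 95–98 across
seeds) and by construction can never beat it — NNI has genuine local
optima on arbitrary (non-treelike) matrices, and the residual few
percent is that, not an implementation defect.

Bootstrap resamples codon columns — blocks of three nucleotide columns —
so replicates stay in frame. Supports are percentages of successful
replicates containing each internal bipartition of the full-data tree;
the conventional 50% display threshold is left to display code.
Replicates whose distances saturate are skipped and excluded from the
denominator. Fixed seed ⇒ identical supports.

## RSCU and site classification

For codon c of an amino acid with k synonymous codons,
R(c) = count(c)/(total(aa)/k), pooled over all records; within every
family with nonzero counts, Σ R = k exactly (property-tested on random
count tables). The not-preferable set is {c : R(c) ≤ threshold}, with
the published inclusive threshold 0.7 as default; methionine and
tryptophan (k = 1) always have R = 1 and are never flagged. Codons of
unobserved amino acids get R = NaN, reported as missing. Reports round R
to 2 decimals; machine output keeps full precision.

Site classification walks the reference row of the codon alignment: a
column is *invariant* when every row shows the reference amino acid and
— by default — no row has a gap there (a gap is not the reference
residue; a residues-only mode is available as a switch). Variant columns
are *compensatory* when the codons observed at the column include a
not-preferable codon, else *forward*. "Observed at the column" means in
any row by default; a reference-codon-only reading is available behind a
flag. The three classes partition the reference residues, raising the
threshold can only move sites forward → compensatory, and the
classification is invariant to row order and row duplication — all
property-tested.

## Landmarks

"Common" features require presence in 100% of rows by default, with a
fraction knob (e.g. 0.9) because per-cluster commonality tolerances were
not published. N-glycosylation sequons N-{P}-[S/T] are evaluated on each
row's own ungapped context so interior alignment gaps do not break a
site. Tripeptide repeats (G-x(2))_n are the longest run of consecutive
triplets with G first residues, scanned in all three phases, allowing up
to `max_mismatch` non-G triplets per run (default 2 — "imperfect" was
not quantified, so this is our choice), trimmed to start and end on a G
triplet, leftmost on ties, reported from n ≥ 2. Splice boundaries are
cumulative exon lengths converted to the codon containing the boundary's
last exonic base, then to alignment columns; per-row columns and their
intersection are both reported, since cross-species boundary jitter
makes either view alone misleading. Signal-peptide cleavage sites are an
external annotation carried through untouched.

## Synthetic generator

The generator emulates the statistical structure the analyses assume,
not sequencing reality. The guide tree is a star of cluster ancestors at
half the between-cluster distance, each carrying a random ultrametric
within-cluster tree (coalescences at sorted uniform heights) of height
half the within-cluster distance — mirroring orthologue clusters
separated by deep divergence. Codon usage bias is per-amino-acid
geometric weights exp(−s·rank) over a randomly permuted family, so
s = 0 gives uniform usage (all R = 1) and the default s = 1.5 yields a
substantial not-preferable set. Evolution is codon-level resampling:
Poisson(3t) events per codon on a branch of length t; an event redraws
the codon from the bias distribution, changing the amino acid (uniform
over the other 19) with probability `nonsyn_fraction` at non-invariant
columns only. Indels are codon-multiple deletions at non-invariant
columns (insertions are deliberately not modelled; deletions exercise
every downstream gap path without ancestral-coordinate bookkeeping).

Two constructions make the truth tables exact rather than approximate:
invariant columns never change amino acid and are never deleted, and —
with `guarantee_variation` (default on) — any non-invariant column that
drifted to a single amino acid across all leaves receives one forced
substitution in a random lineage. Defaults (3 clusters × 5 taxa, 120
codons, within-distance 0.05, between-distance 1.0, invariant fraction
0.25, bias 1.5, no indels) are the study conditions of the test suite
and acceptance script.

Read simulation tiles every contiguous allowed segment end-to-end (so
error-free coverage outside engineered dropout intervals is guaranteed
nonzero) and adds uniformly placed reads to reach the target expected
depth; no read ever overlaps a dropout, strands are random, and errors
are i.i.d. substitutions. This emulates archival read redundancy, not
real error profiles, quality values, or indel errors.

Because the generator is i.i.d. at the codon level with a star-of-
clusters tree, passing tests demonstrate correctness of the statistics
and search machinery under the assumed structure — they do not
demonstrate robustness to alignment error, recombination, rate
heterogeneity across sites or lineages, or base-composition drift,
none of which the generator produces.

## Problem sizes and determinism

The default suite and acceptance script run families of 15–20 sequences
of 120 codons, 100 bootstrap replicates, and 100 random 6-taxon
matrices against the exhaustive 105-topology oracle — sizes chosen so
every check is exact or ensemble-stable while the whole protocol runs
in seconds. All randomness flows from explicit integer seeds through
per-purpose substreams; the pipeline writes SHA-256 checksums of every
output, and reruns with the same config and seed are byte-identical.

## Known limitations

- The reliability mapper is ungapped and k-mer seeded: reads spanning
  true indels or with errors in every seeding k-mer are dropped.
- `TN93_pooled` is an approximation; it is not claimed to match any
  specific program's composite-likelihood output digit-for-digit.
- NNI descent can stop in local optima on non-treelike matrices (a few
  percent of random cases at 6 taxa).
- Alignment-dependent published values can only be reproduced
  approximately from re-derived alignments, since the published
  alignment was manually corrected.
- The 438 → 211 complete/putative outcome of the original curation is
  not reproducible from deposited data (it required archival reads);
  the reliability stage is validated on synthetic truth instead.
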