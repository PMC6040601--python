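# adiclade

Comparative genomic analysis of multi-cluster gene families, built around
the protocol used for the curated eutherian adiponectin (*ADI*) gene data
set (ENA accessions LT962964–LT963174: 211 complete coding sequences in
18 major gene clusters ADIA–ADIR).

The package is for researchers curating gene families across many
genomes who need to (i) decide which candidate coding sequences are
trustworthy before analysing them, and (ii) characterize the family's
molecular evolution with transparent, reproducible statistics. It
implements:

- **Reliability testing** — a candidate CDS is *complete* only when every
  nucleotide has consensus-agreeing coverage from genomic sequence reads
  (a base counts as supported only by read placements that match the CDS
  base there); anything less is *putative* and excluded.
- **Codon-aware alignments** — protein alignments (from any external
  aligner) threaded with the source nucleotides, one codon per residue,
  validated bit-exactly.
- **Identity statistics** — for each aligned set, the mean pairwise
  identity *ā*, its mean absolute deviation *ā*_ad, and extremes *a*_max
  and *a*_min over all n(n−1)/2 pairs, with homologue-pattern labels from
  "very close" to "very distant".
- **Minimum-evolution phylogenetics** — pairwise distances (p, JC, or a
  pooled-parameter TN93 approximation of composite-likelihood distances;
  pairwise deletion throughout), neighbor-joining start, OLS branch
  lengths, NNI descent on the total tree length S, and codon-column
  bootstrap supports.
- **RSCU site classification** — relative synonymous codon usage
  R(c) = count(c) / (total(aa)/k) pooled over the data set; codons with
  R ≤ 0.7 form the *not-preferable* set; each reference residue is then
  *invariant* (one amino acid in every row), *forward* (variant, no
  not-preferable codon observed at the column) or *compensatory*
  (variant, at least one not-preferable codon observed).
- **Protein landmarks** — common cysteines, N-glycosylation sequons
  N-{P}-[S/T], exon–intron splice-site columns, and collagen-like
  (G-x(2))_n tripeptide repeat regions, cross-tabulated with the site
  classes.
- **A synthetic gene-family generator** with exact truth tables
  (generating tree, invariant columns, cluster assignments, engineered
  coverage gaps), so every stage is verifiable without downloading data.

## Worked example

```python
from adiclade import (SimulationConfig, simulate_family, thread_nucleotides,
                      summarize_alignment, codon_usage, rscu, classify_sites)
from adiclade.phylogeny import bootstrap, cluster_groups

family, truth = simulate_family(SimulationConfig(seed=42))
aln = thread_nucleotides(truth.protein_alignment, family.records)
rows = list(zip(aln.record_ids, aln.nucleotide_rows))

print(summarize_alignment(rows))
tree = bootstrap(rows, model="TN93_pooled", replicates=100, seed=42)
print(cluster_groups(tree, truth.cluster_assignment).monophyletic)
table = rscu(codon_usage(family.records))
cls = classify_sites(aln, family.records[0].record_id, table)
print(cls.n_invariant, cls.n_forward, cls.n_compensatory)
```

prints

```
a_bar=0.645 (a_max=0.994, a_min=0.478, a_bar_ad=0.182)
{'CLA': True, 'CLB': True, 'CLC': True}
30 57 33
```

meaning: across the 15 simulated sequences the mean pairwise nucleotide
identity is 0.645 (dominated by distant between-cluster pairs; the
within-cluster summaries are ≈ 0.96, "very close"); the
minimum-evolution tree recovers all three planted clusters as
monophyletic; and of the 120 reference residues, 30 are invariant —
exactly the 25% of codon columns the simulation froze — while the 90
variant sites split into 57 forward and 33 compensatory according to
whether rare codons (R ≤ 0.7) occur at the column.

The `examples/` directory holds one short script per capability;
`adiclade demo --seed 7 --out demo/` runs the whole protocol end to end
on synthetic data and writes TSV/newick reports plus a checksummed
manifest.

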