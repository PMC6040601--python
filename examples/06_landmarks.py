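"""Protein primary-structure landmarks on an alignment.

Finds cysteines shared by all rows, common N-glycosylation sequons
(N-{P}-[S/T]), splice-site columns from exon annotations, and the
collagen-like (G-x(2))_n tripeptide repeat region.
"""

from adiclade import SimulationConfig, annotate, simulate_family, thread_nucleotides
from adiclade.landmarks import find_tripeptide_repeats

family, truth = simulate_family(SimulationConfig(seed=42))
aln = thread_nucleotides(truth.protein_alignment, family.records)

lm = annotate(aln, family.records)
print(f"common cysteine columns: {lm.common_cysteines}")
print(f"common N-glycosylation sequon columns: {lm.glyco_sites}")

# a collagen-like stretch, as seen in real adiponectin-family N-termini:
collagen_like = "MKLV" + "GPPGEPGKH" * 8 + "ACDEF"
rep = find_tripeptide_repeats(collagen_like, max_mismatch=2)
print(f"synthetic collagen-like region: residues {rep.start}-{rep.end}, "
      f"n = {rep.n} tripeptides")
# Landmarks are reported as 1-based alignment columns and are the
# features cross-tabulated with invariant sites in the site report.
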