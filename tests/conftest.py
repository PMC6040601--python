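import pytest

from adiclade.codon_align import thread_nucleotides
from adiclade.simulate import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """A 3-cluster x 5-taxon simulated family with truth tables."""
    return simulate_family(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_alignment(small_family):
    """The family's true protein alignment threaded with nucleotides."""
    family, truth = small_family
    return thread_nucleotides(truth.protein_alignment, family.records)


MINI_EMBL = """\
ID   TEST1; SV 1; linear; mRNA; STD; MAM; 9 BP.
XX
DE   Homo sapiens ADIF2 mRNA for adiponectin-like protein
XX
OS   Homo sapiens (human)
OC   Eukaryota; Metazoa.
XX
FH   Key             Location/Qualifiers
FH
FT   CDS             1..9
FT                   /gene="ADIF2"
XX
SQ   Sequence 9 BP; 3 A; 2 C; 4 G; 0 T; 0 other;
     atggctgga                                                                 9
//
"""

MINI_EMBL_NO_OS = """\
ID   TEST2; SV 1; linear; mRNA; STD; MAM; 6 BP.
XX
DE   synthetic entry without organism line
XX
SQ   Sequence 6 BP; 2 A; 1 C; 2 G; 1 T; 0 other;
     atggga                                                                    6
//
"""


@pytest.fixture
def mini_embl(tmp_path):
    p = tmp_path / "mini.embl"
    p.write_text(MINI_EMBL)
    return p


@pytest.fixture
def mini_embl_no_os(tmp_path):
    p = tmp_path / "no_os.embl"
    p.write_text(MINI_EMBL_NO_OS)
    return p
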