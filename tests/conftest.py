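import numpy as np
import pytest

from dockmap import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def complex_fixture():
    """A designed binary complex (64 + 48 residues) with a packed interface."""
    return synth.make_complex(seed=1)


@pytest.fixture(scope="session")
def compact_chain():
    rng = np.random.default_rng(7)
    ca = synth.serpentine_ca(64)
    return synth.chain_from_ca(ca, synth.random_sequence(64, rng), "A",
                               uniprot_acc="P10001")


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      5  CA  TRP A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB
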