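import numpy as np
import pytest

from axialkit import ROD_SYMMETRY, ToySubunitSpec, build_assembly, make_toy_subunit

# minimal hand-written two-residue PDB fixture (one chain)
TOY_PDB = """\
CRYST1   47.500   67.000  110.300  90.00  90.00  90.00 P 21 21 21
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.167  -4.935  1.00  0.00           C
ATOM      4  O   ALA A   1      13.549   7.369  -5.792  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.217   4.682  -4.864  1.00  0.00           C
ATOM      6  N   GLY A   2      12.609   7.885  -3.815  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.562   8.961  -3.541  1.00  0.00           C
ATOM      8  C   GLY A   2      13.021   9.878  -2.450  1.00  0.00           C
ATOM      9  O   GLY A   2      11.823   9.897  -2.169  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture(scope="session")
def toy_subunit():
    return make_toy_subunit(ToySubunitSpec(seed=0))


@pytest.fixture(scope="session")
def rod_assembly(toy_subunit):
    """33-subunit toy rod: subunit 0 is interior out to offset +-16."""
    return build_assembly(toy_subunit, ROD_SYMMETRY, (-16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
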