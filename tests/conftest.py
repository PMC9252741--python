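import numpy as np
import pytest

from surfpatch.fixtures import make_test_meshes, make_toy_dimer, make_toy_pocket
from surfpatch.structure import parse_pdb, assign_typing


ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.166  -4.944  1.00  0.00           C
ATOM      4  O   ALA A   1      12.977   7.950  -5.848  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.497   6.178  -4.128  1.00  0.00           C
"""


@pytest.fixture(scope="session")
def test_meshes():
    return make_test_meshes()


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(seed=0)


@pytest.fixture(scope="session")
def toy_pocket():
    return make_toy_pocket("HEM", seed=0)


@pytest.fixture(scope="session")
def ala_structure():
    return assign_typing(parse_pdb(ALA_PDB))


def single_atom_pdb(element="C", name="CA", x=0.0, y=0.0, z=0.0, serial=1,
                    res_id=1):
    return (
        f"ATOM  {serial:5d} {name:^4s} ALA A{res_id:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
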