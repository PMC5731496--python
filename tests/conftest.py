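import numpy as np
import pytest

from conftop import CalphaStructure, toy_chain_pair


@pytest.fixture(scope="session")
def toy_pair():
    """Deterministic 10-residue start/goal chain pair."""
    return toy_chain_pair(10, 20, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def zigzag():
    """Planar zig-zag chain: all pseudo-dihedrals are 180 degrees."""
    coords = np.array([[i * 3.0, (i % 2) * 2.0, 0.0] for i in range(8)])
    return CalphaStructure("zigzag", np.arange(1, 9), coords)


PDB_THREE_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       5.500   3.400   0.000  1.00  0.00           C
TER
END
"""

PDB_NO_CA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  C   ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  N   ALA A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      4  C   ALA A   2       5.300   0.000   0.000  1.00  0.00           C
TER
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture()
def pdb_three_ca():
    return PDB_THREE_CA


@pytest.fixture()
def pdb_no_ca():
    return PDB_NO_CA


@pytest.fixture()
def pdb_altloc():
    return PDB_ALTLOC
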