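import numpy as np
import pytest

from prsda import generate_synthetic_native
from prsda.structure_io import BackboneStructure

TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.458   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.010   3.420   3.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.270   4.400   3.100  1.00  0.00           O
ATOM      5  N   GLY A   2       4.330   3.540   2.900  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.970   4.850   2.850  1.00  0.00           C
ATOM      7  C   GLY A   2       6.480   4.700   2.750  1.00  0.00           C
ATOM      8  O   GLY A   2       7.010   3.590   2.700  1.00  0.00           O
TER       9      GLY A   2
END
"""

TWO_RESIDUE_COORDS = np.array(
    [
        [[1.000, 2.000, 3.000], [2.458, 2.000, 3.000],
         [3.010, 3.420, 3.000], [2.270, 4.400, 3.100]],
        [[4.330, 3.540, 2.900], [4.970, 4.850, 2.850],
         [6.480, 4.700, 2.750], [7.010, 3.590, 2.700]],
    ]
)


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_res.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def two_residue_structure():
    return BackboneStructure(sequence="AG", coords=TWO_RESIDUE_COORDS.copy(), id="two")


@pytest.fixture(scope="session")
def helix30():
    return generate_synthetic_native(30, "helix", seed=1)


@pytest.fixture(scope="session")
def mixed60():
    return generate_synthetic_native(60, "mixed", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
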