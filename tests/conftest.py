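import numpy as np
import pytest

from modetrap.enm import ENMPreset, build_network, diagonalize
from modetrap.structure import structure_from_arrays
from modetrap.toys import make_helix, make_two_domain


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture(scope="session")
def helix_modes(helix12):
    return diagonalize(build_network(helix12, ENMPreset(kind="cutoff", cutoff=8.0)))


@pytest.fixture(scope="session")
def two_domain():
    return make_two_domain(12, 8)


@pytest.fixture(scope="session")
def two_domain_modes(two_domain):
    return diagonalize(build_network(two_domain.structure, ENMPreset()))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_cloud(rng):
    """A 10-atom aperiodic point cloud (superposition / RMSD fixtures)."""
    return structure_from_arrays(rng.uniform(-8, 8, size=(10, 3)))


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   3.300   3.000  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "three_atoms.pdb"
    p.write_text(MINIMAL_PDB)
    return p
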