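import numpy as np
import pytest

from modelqa.decoy_sim import SimConfig, generate_native
from modelqa.structure_model import ProteinModel, Residue


THREE_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  ALA A   2       4.021   2.792   0.230  1.00  0.00           C
ATOM      6  C   ALA A   2       5.490   2.590   0.590  1.00  0.00           C
ATOM      7  N   GLY A   3       6.210   3.690   0.720  1.00  0.00           N
ATOM      8  CA  GLY A   3       7.640   3.660   1.010  1.00  0.00           C
ATOM      9  C   GLY A   3       8.380   4.940   0.660  1.00  0.00           C
TER
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "gag.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture(scope="session")
def helix_native():
    return generate_native(SimConfig(L=10, template="helix", seed=7))


@pytest.fixture(scope="session")
def mixed_native():
    return generate_native(SimConfig(L=30, template="mixed", seed=7))


def make_ca_model(coords, sequence=None, model_id="toy"):
    """Build a CA-only ProteinModel from an (L, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if sequence is None:
        sequence = "A" * len(coords)
    residues = [
        Residue(index=i + 1, aa=sequence[i], atoms={"CA": coords[i]})
        for i in range(len(coords))
    ]
    return ProteinModel(model_id=model_id, residues=residues)


def random_rigid_transform(rng):
    """Random proper rotation + translation for invariance checks."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-30, 30, size=3)
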