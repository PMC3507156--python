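import numpy as np
import pytest

from triadcore.structure_io import read_pdb
from triadcore.synthetic import make_ideal_ca_trace, perturb_with_core

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.023   2.772   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.535   2.612   0.100  1.00  0.00           C
ATOM      7  N   SER A   3       6.240   3.728   0.200  1.00  0.00           N
ATOM      8  CA  SER A   3       7.693   3.711   0.300  1.00  0.00           C
ATOM      9  C   SER A   3       8.260   5.121   0.400  1.00  0.00           C
TER      10
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def minimal_structure(minimal_pdb):
    return read_pdb(minimal_pdb)


def random_rigid_transform(rng):
    """A uniform-ish random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-30, 30, size=3)


@pytest.fixture
def planted_core_pair():
    """Reference structure + factory for perturbed copies with known core."""
    topology = [("helix", 20), ("loop", 10), ("strand", 10), ("loop", 10),
                ("helix", 20), ("loop", 10), ("strand", 10), ("loop", 10),
                ("helix", 20)]
    ref = make_ideal_ca_trace(topology, structure_id="core_ref")
    kinds = [k for k, n in topology for _ in range(n)]
    core_mask = np.array([k != "loop" for k in kinds])

    def perturb(seed, noise_sigma=0.2, loop_displacement=5.0, rigid=None):
        return perturb_with_core(ref, core_mask, noise_sigma,
                                 loop_displacement, rigid=rigid, seed=seed)

    return ref, core_mask, perturb
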