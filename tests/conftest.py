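import numpy as np
import pytest

import solidnma as s

PDB_FIXTURE = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       30.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00 11.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00 11.50           C
ATOM      4  O   GLY A   1       1.500   2.300   0.700  1.00 12.00           O
ATOM      5  H   GLY A   1       0.500  -0.800   0.000  1.00  5.00           H
ATOM      6  CA AALA A   2       3.500   1.600   1.000  0.60 12.00           C
ATOM      7  CA BALA A   2       3.450   1.650   1.050  0.40 12.50           C
ATOM      8  CA  TRP A   3       5.000   2.600   2.000  1.00 13.00           C
ATOM      9  CA  LYS A   4       6.300   3.600   3.200  1.00 14.00           C
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(PDB_FIXTURE)
    return path


@pytest.fixture(scope="session")
def lattice3():
    return s.make_lattice(3)


@pytest.fixture(scope="session")
def lattice3_system(lattice3):
    mesh = s.build_alpha_shape(lattice3, 10.0)
    params = s.ElasticParams.for_mesh(mesh, lattice3.total_mass, E=1.0, nu=0.3)
    return s.assemble(mesh, params)


@pytest.fixture(scope="session")
def lattice3_allmodes(lattice3_system):
    return s.solve_modes(lattice3_system, n_modes=lattice3_system.n_dof)


@pytest.fixture(scope="session")
def helix_system():
    """A protein-like Cα trace with a solid model and full mode set."""
    pts = s.make_helix(n_residues=50, seed=11)
    mesh = s.build_alpha_shape(pts, None)
    params = s.ElasticParams.for_mesh(mesh, pts.total_mass)
    return pts, mesh, s.assemble(mesh, params)


def rigid_basis(coords):
    """Six rigid-body vectors: 3 translations + 3 rotations about centroid."""
    n = len(coords)
    c = coords - coords.mean(axis=0)
    basis = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = 1.0
        basis.append(t.reshape(-1))
    for axis in np.eye(3):
        basis.append(np.cross(axis, c).reshape(-1))
    return np.array(basis).T  # (3n, 6)
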