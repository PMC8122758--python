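import numpy as np
import pytest

from plifdet import fixtures
from plifdet.ensplif import EnsPlifRow, EnsPlifTable
from plifdet.structio import Atom

TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.460  -0.600   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.350  -0.700   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.450  -1.930   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.000   1.530   0.000  1.00  0.00           C
ATOM      6  N   GLY A   2       3.540  -0.600   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       6.350  -0.700   0.000  1.00  0.00           C
ATOM      9  O   SER A   3       9.450  -1.930   0.000  1.00  0.00           O
HETATM   10  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       0.000   1.530   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1       9.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER B   2      12.000   0.000   0.000  1.00  0.00           C
ATOM      5  CB  SER B   2      12.000   1.530   0.000  1.00  0.00           C
END
"""

TOY_PDBQT = """\
MODEL 1
REMARK VINA RESULT:    -9.1      0.000      0.000
ATOM      1  C1  LIG     1       0.000   0.000   0.000  1.00  0.00     0.031 C
ATOM      2  N1  LIG     1       1.400   0.000   0.000  1.00  0.00    -0.250 NA
ENDMDL
MODEL 2
REMARK VINA RESULT:    -8.7      1.200      2.100
ATOM      1  C1  LIG     1       0.100   0.000   0.000  1.00  0.00     0.031 C
ATOM      2  N1  LIG     1       1.500   0.000   0.000  1.00  0.00    -0.250 NA
ENDMDL
MODEL 3
REMARK VINA RESULT:    -8.2      2.000      3.500
ATOM      1  C1  LIG     1       0.200   0.000   0.000  1.00  0.00     0.031 C
ATOM      2  N1  LIG     1       1.600   0.000   0.000  1.00  0.00    -0.250 NA
ENDMDL
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


@pytest.fixture
def toy_pdbqt(tmp_path):
    path = tmp_path / "poses.pdbqt"
    path.write_text(TOY_PDBQT)
    return path


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_table1_fixture()


def make_atom(coords, element="C", name=None, serial=1, resname="LIG",
              resnum=1, chain=" ", backbone=False):
    atom = Atom(serial=serial, name=name or element, element=element,
                coords=np.asarray(coords, dtype=float), residue_number=resnum,
                residue_name=resname, chain_id=chain, is_hetatm=resname == "LIG")
    atom.is_backbone = backbone
    return atom


def simple_table(v_matrix, y, dg=None):
    """EnsPlifTable from a raw V matrix and labels."""
    v_matrix = np.asarray(v_matrix, dtype=float)
    dg = dg if dg is not None else [-8.0] * len(y)
    rows = [EnsPlifRow(int(y[i]), f"cmpd{i:04d}", float(dg[i]), v_matrix[i])
            for i in range(len(y))]
    return EnsPlifTable(rows=rows)


@pytest.fixture
def separable_table():
    """40 rows, one variable: V1 >= ~0.5 perfectly separates actives."""
    rng = np.random.default_rng(3)
    v = np.concatenate([rng.uniform(0.6, 1.0, 20), rng.uniform(0.0, 0.4, 20)])
    y = [1] * 20 + [0] * 20
    return simple_table(v[:, None], y)
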