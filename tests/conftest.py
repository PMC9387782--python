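"""Shared fixtures: hand-written PDB text, toy bead complexes, ensembles."""

import numpy as np
import pytest

from trajthermo.model_io import Selection
from trajthermo.synthetic import ToyComplexSpec, gen_toy_complex

# hand-written minimal PDB: one GLY Calpha, one Zn ion, one ligand carbon
THREE_ATOM_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2 ZN    ZN A  90       2.000   0.000   0.000  1.00  0.00          ZN
HETATM    3  C1  LIG A  91       0.000   3.000   0.000  1.00  0.00           C
END
"""

PARAMS_TSV = """\
residue_name\tatom_name\tmass\tcharge\tsigma\tepsilon\tpb_radius
ZN\tZN\t65.4\t2.0\t1.96\t0.0125\t1.39
GLY\tCA\t12.011\t-0.1\t3.4\t0.1\t1.7
LIG\tC1\t12.011\t0.3\t3.4\t0.1\t1.7
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def params_sidecar(tmp_path):
    p = tmp_path / "params.tsv"
    p.write_text(PARAMS_TSV)
    return p


@pytest.fixture
def toy_complex():
    """2 protein beads + 1 ligand bead, charges (+1, -1, +1) e."""
    spec = ToyComplexSpec(
        protein_coords=np.array([[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]]),
        ligand_coords=np.array([[1.75, 3.2, 0.0]]),
        protein_charges=np.array([1.0, -1.0]),
        ligand_charges=np.array([1.0]),
        lj_sigma=3.4, lj_epsilon=0.1, pb_radius=1.7,
    )
    return gen_toy_complex(spec)


@pytest.fixture
def toy_selections(toy_complex):
    prot = Selection((0, 1), "protein")
    lig = Selection((2,), "ligand")
    return prot, lig
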