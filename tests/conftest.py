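import numpy as np
import pytest

from curvmap.structures import AtomRecord, Structure
from curvmap.synthetic import make_toy_protein, sphere_mesh

GLY_PDB = """\
ATOM      1  N   GLY H   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY H   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY H   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA H  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA H  11       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY L   5       0.000   5.000   0.000  1.00  0.00           C
END
"""


def multi_model_pdb(n_models: int, n_atoms: int = 10, drop_last_atom_in=None) -> str:
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        count = n_atoms - (1 if drop_last_atom_in == m else 0)
        for i in range(count):
            x = i * 3.8 + 0.01 * m
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ALA H{i + 1:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def single_atom(radius: float = 1.5, f: float = 0.7, q: float = 0.0,
                coords=(0.0, 0.0, 0.0)) -> Structure:
    return Structure(
        [
            AtomRecord(
                1, "C", "CA", np.asarray(coords, float), ("H", 1, ""), "GLY",
                radius=radius, partial_charge=q, hydrophobicity=f,
            )
        ]
    )


def atom_cluster(coords, radii=None, charges=None, hydros=None) -> Structure:
    coords = np.asarray(coords, float)
    n = len(coords)
    radii = np.full(n, 1.5) if radii is None else np.asarray(radii, float)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    hydros = np.zeros(n) if hydros is None else np.asarray(hydros, float)
    return Structure(
        [
            AtomRecord(
                i + 1, "C", "CA", coords[i], ("H", i + 1, ""), "GLY",
                radius=radii[i], partial_charge=charges[i], hydrophobicity=hydros[i],
            )
            for i in range(n)
        ]
    )


@pytest.fixture(scope="session")
def sphere_r10():
    """Icosphere R=10 Å with closed-form curvature ground truth."""
    return sphere_mesh(radius=10.0, subdivisions=3)


@pytest.fixture(scope="session")
def toy_globule():
    return make_toy_protein(n_atoms=20, motif="globule", seed=7)


@pytest.fixture()
def gly_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLY_PDB)
    return p


@pytest.fixture()
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p
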