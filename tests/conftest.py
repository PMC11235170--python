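import numpy as np
import pytest

from tandemrrm import gomodel as gm
from tandemrrm import structcore as sc
from tandemrrm.synthetic_data import gen_toy_structure

# 3-atom hand-written PDB (one alanine fragment)
TINY_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       3.000   3.400   3.000  1.00  0.00           C
END
"""

# one atom with two alternate locations A/B
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA AALA A   1       2.500   2.000   3.000  0.60  0.00           C
ATOM      3  CA BALA A   1       2.600   2.100   3.000  0.40  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def helix_model():
    return gen_toy_structure("helix", 12)


@pytest.fixture(scope="session")
def hairpin_model():
    return gen_toy_structure("hairpin", 11)


@pytest.fixture(scope="session")
def hairpin_system(hairpin_model):
    return gm.build_go_system(hairpin_model, contact_cutoff=4.7, min_separation=3)


@pytest.fixture(scope="session")
def helix_system(helix_model):
    return gm.build_go_system(helix_model, contact_cutoff=6.0, min_separation=3)


@pytest.fixture(scope="session")
def hairpin_scan(hairpin_system):
    """One modest multi-temperature scan reused across WHAM tests."""
    temps = np.arange(0.35, 1.06, 0.1)
    return gm.run_scan(
        hairpin_system, temps, 120000, seed=11, dt=0.01, friction=0.3
    )


def two_residue_model(distance: float) -> sc.StructureModel:
    """Two alanines whose CB atoms sit exactly `distance` apart."""
    return sc.StructureModel(
        chain=["A"] * 4,
        resnum=[1, 1, 2, 2],
        resname=["ALA"] * 4,
        atomname=["CA", "CB", "CA", "CB"],
        element=["C"] * 4,
        coords=[
            [-2.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],            # CB of residue 1
            [distance + 2.0, 0.0, 0.0],
            [distance, 0.0, 0.0],       # CB of residue 2
        ],
    )
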