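import numpy as np
import pytest

from molcanvas import (
    assign_elements_and_radii,
    assign_secondary_structure,
    parse_pdb,
    parse_pdbqt,
)
from molcanvas.fixtures import FixtureSpec, synth_pdb, synth_pdbqt


def load_pdb(text):
    s = parse_pdb(text)
    assign_elements_and_radii(s)
    assign_secondary_structure(s)
    return s


@pytest.fixture
def helix_structure():
    """12-residue ideal alpha-helix C-alpha trace with a HELIX record."""
    return load_pdb(synth_pdb(FixtureSpec("mini_helix", {"n": 12})))


@pytest.fixture
def diatomic():
    """Factory: two-atom PDB structure at a given separation."""
    def make(separation=3.4, elements=("N", "O"), hetero=False):
        return load_pdb(synth_pdb(FixtureSpec(
            "diatomic", {"separation": separation, "elements": elements,
                         "hetero": hetero})))
    return make


@pytest.fixture
def blob_structure():
    """12-atom hetero ligand blob with exact extents (10, 6, 4) A."""
    return load_pdb(synth_pdb(FixtureSpec(
        "ligand_blob", {"extents": (10.0, 6.0, 4.0), "n": 12}, seed=7)))


@pytest.fixture
def docked():
    """3-model docked ensemble with energies and polar atoms."""
    text = synth_pdbqt(FixtureSpec(
        "docked_ensemble", {"k": 3, "energies": [-9.1, -8.4, -7.9]}))
    return parse_pdbqt(text)


@pytest.fixture
def single_atom():
    """Factory: one-atom structure with a chosen van der Waals radius."""
    def make(radius=2.0, center=(0.0, 0.0, 0.0)):
        s = load_pdb(synth_pdb(FixtureSpec(
            "sphere_cluster", {"centers": [center], "elements": ["C"]})))
        s.atoms[0].vdw_radius = radius
        return s
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20241)
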