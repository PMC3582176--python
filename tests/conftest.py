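import numpy as np
import pytest

from excitoncd import load_parameter_set, write_structure
from excitoncd.structure_io import Atom, Chain, ChromophoreType, Model, Residue, Structure
from excitoncd.synthetic_data import synthetic_hcaii_like_structure


@pytest.fixture(scope="session")
def params():
    return load_parameter_set()


def _trp_residue(seqnum: int, centroid, params, spin_deg: float = 0.0):
    from scipy.spatial.transform import Rotation

    template = params[ChromophoreType.TRP_INDOLE].template_atoms
    R = Rotation.from_euler("z", spin_deg, degrees=True).as_matrix()
    atoms = [
        Atom(name, "N" if name.startswith("N") else "C",
             R @ xyz + np.asarray(centroid, float))
        for name, xyz in template.items()
    ]
    atoms.append(Atom("CA", "C", np.asarray(centroid, float) + [0.0, 0.0, 2.4]))
    return Residue("TRP", seqnum, "A", atoms)


def _ala_residue(seqnum: int, x: float):
    return Residue("ALA", seqnum, "A", [Atom("CA", "C", np.array([x, 0.0, 0.0]))])


@pytest.fixture(scope="session")
def ala_trp_ala(params) -> Structure:
    """Three-residue Ala-Trp-Ala structure with an ideal indole ring."""
    residues = [
        _ala_residue(1, -8.0),
        _trp_residue(2, (0.0, 0.0, 0.0), params),
        _ala_residue(3, 8.0),
    ]
    return Structure(models=[Model([Chain("A", residues)])], source_id="awa")


@pytest.fixture(scope="session")
def ala_trp_ala_pdb(ala_trp_ala, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "ala_trp_ala.pdb"
    write_structure(ala_trp_ala, path)
    return path


@pytest.fixture(scope="session")
def two_trp_structure(params) -> Structure:
    """Two tryptophans 8 Å apart with different ring orientations."""
    residues = [
        _trp_residue(1, (0.0, 0.0, 0.0), params, spin_deg=0.0),
        _trp_residue(2, (8.0, 0.0, 1.0), params, spin_deg=75.0),
    ]
    return Structure(models=[Model([Chain("A", residues)])], source_id="trp2")


@pytest.fixture(scope="session")
def two_trp_pdb(two_trp_structure, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "two_trp.pdb"
    write_structure(two_trp_structure, path)
    return path


@pytest.fixture(scope="session")
def hcaii_like() -> Structure:
    return synthetic_hcaii_like_structure()


@pytest.fixture(scope="session")
def hcaii_like_pdb(hcaii_like, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "synthetic_hcaii_like.pdb"
    write_structure(hcaii_like, path)
    return path
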