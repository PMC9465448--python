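import warnings

import numpy as np
import pytest

import biotite.structure.info as bstinfo

from hbdock.fixtures import FixtureSpec, make_ideal_helix, make_planted_complex
from hbdock.rotamers import load_library
from hbdock.structure import Atom, ProteinStructure, Residue


def pytest_configure(config):
    # gemmi/biotite emit benign deprecation chatter on some inputs
    warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def library():
    return load_library()


def residue_from_template(aa_type: str, chain_id: str = "A", res_seq: int = 1,
                          shift=(0.0, 0.0, 0.0)) -> Residue:
    """Residue built from the ideal-geometry component dictionary entry,
    heavy atoms only, with names mapped to the CHARMM convention."""
    tmpl = bstinfo.residue(aa_type)
    rename = {"OXT": "OT2"}
    if aa_type in ("SER", "CYS"):
        rename["HG"] = "HG1"
    atoms = []
    for name, element, coord in zip(tmpl.atom_name, tmpl.element,
                                    tmpl.coord.astype(float)):
        if element == "H":
            continue
        atoms.append(Atom(rename.get(str(name), str(name)), str(element),
                          coord + np.asarray(shift, float)))
    return Residue(chain_id, res_seq, aa_type, atoms)


@pytest.fixture()
def ala_site() -> ProteinStructure:
    """A single-residue structure providing a backbone frame."""
    return ProteinStructure([residue_from_template("ALA")])


@pytest.fixture(scope="session")
def small_helix():
    return make_ideal_helix("AASAAASAAA")


@pytest.fixture(scope="session")
def planted3():
    """Zero-noise fixture with three planted bonds plus its ground truth."""
    spec = FixtureSpec(n_planted_bonds=3, seed=1)
    scaffold, antigen, expected = make_planted_complex(spec)
    return scaffold, antigen, expected


def bond_keys(expected):
    return {(tuple(s) + (a,), tuple(e) + (o,)) for (s, a), (e, o) in expected}


def pose_bond_keys(pose):
    return {(pbr.site + (pbr.atom_name,), eba.site + (eba.atom_name,))
            for pbr, eba in pose.group.interactions}
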