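"""Synthetic scaffold/antigen systems with analytically known geometry.

The generator builds an ideal alpha-helical scaffold (the shape of the
helical binding faces of small fixed-backbone scaffolds) and plants short
antigen peptide fragments so that a chosen number of scaffold donor
half-sites see an antigen backbone carbonyl exactly at their ideal partner
position.  Because the construction is closed-form, the set of interface
hydrogen bonds a docking run should recover is known exactly, which makes
every pipeline stage testable without any external structure files.

Generation is a pure function of the fixture spec (including its seed).
"""
from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import place_internal, superpose_points, unit
from .hbond import make_pbrs, PBR
from .hydrogens import add_hydrogens
from .rotamers import load_library, place_rotamer, install_rotamer
from .structure import Atom, ProteinStructure, Residue, Site

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal backbone internal coordinates (A / deg)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8

#: donor-site positions on one helix face (i, i+4, i+7, ... pattern)
_FACE_POSITIONS = (3, 7, 10, 14, 17, 21, 24, 28)


@dataclasses.dataclass
class FixtureSpec:
    n_planted_bonds: int = 3
    donor_types: Optional[Sequence[str]] = None  # scaffold donors, default SER
    acceptor_types: Optional[Sequence[str]] = None  # fragment residues, default ALA
    geometric_noise: float = 0.0  # A, displacement applied to each fragment
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_bonds < 0:
            raise ValueError("n_planted_bonds must be >= 0")
        if self.geometric_noise < 0:
            raise ValueError("geometric noise must be >= 0")
        if self.n_planted_bonds > len(_FACE_POSITIONS):
            raise ValueError(
                f"at most {len(_FACE_POSITIONS)} bonds can be planted")


def _build_backbone(n_residues: int, phi: float, psi: float,
                    start: np.ndarray) -> List[dict]:
    """Backbone N/CA/C/O coordinates for an ideal (phi, psi) chain."""
    res: List[dict] = []
    n = start + np.zeros(3)
    ca = n + np.array([_N_CA, 0.0, 0.0])
    c = place_internal(n + np.array([0.0, 1.0, 0.0]), n, ca,
                       _CA_C, _ANG_N_CA_C, 0.0)
    for i in range(n_residues):
        entry = {"N": n, "CA": ca, "C": c}
        n_next = place_internal(n, ca, c, _C_N, _ANG_CA_C_N, psi)
        entry["O"] = place_internal(n_next, ca, c, _C_O, _ANG_CA_C_O, 180.0)
        res.append(entry)
        if i + 1 < n_residues:
            ca_next = place_internal(ca, c, n_next, _N_CA, _ANG_C_N_CA, 180.0)
            c_next = place_internal(c, n_next, ca_next, _CA_C, _ANG_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
    return res


def _build_chain(sequence: str, chain_id: str, phi: float, psi: float,
                 start=(0.0, 0.0, 0.0), first_seq: int = 1,
                 library=None, rotamer_choice=None) -> ProteinStructure:
    """Ideal-geometry peptide with side chains from the rotamer library.

    ``rotamer_choice`` maps residue index (0-based) to a rotamer index;
    the library's first (most probable) rotamer is used otherwise.
    """
    library = library or load_library()
    backbone = _build_backbone(len(sequence), phi, psi, np.asarray(start, float))
    residues = []
    for i, letter in enumerate(sequence):
        aa = AA_1TO3[letter.upper()]
        atoms = [Atom(name, name[0], backbone[i][name])
                 for name in ("N", "CA", "C", "O")]
        residues.append(Residue(chain_id, first_seq + i, aa, atoms))
    structure = ProteinStructure(residues, source=f"ideal:{sequence}")
    for i, letter in enumerate(sequence):
        aa = AA_1TO3[letter.upper()]
        if aa == "GLY":
            continue
        idx = (rotamer_choice or {}).get(i, 0)
        placed = place_rotamer(structure, (chain_id, first_seq + i),
                               library[aa][idx])
        install_rotamer(structure, placed)
    return add_hydrogens(structure)


def make_ideal_helix(sequence: str, start_coord=(0.0, 0.0, 0.0),
                     chain_id: str = "A", library=None,
                     rotamer_choice=None) -> ProteinStructure:
    """Ideal alpha-helix (phi = -57, psi = -47) with full side chains and
    polar hydrogens."""
    return _build_chain(sequence, chain_id, -57.0, -47.0, start_coord,
                        library=library, rotamer_choice=rotamer_choice)


def _helix_axis(structure: ProteinStructure):
    ca = np.array([r.atom("CA").coord for r in structure.residues])
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    return center, vt[0]


def _outward(structure: ProteinStructure, site: Site) -> np.ndarray:
    center, axis = _helix_axis(structure)
    res = structure[site]
    anchor = res.atom("CB").coord if res.has_atom("CB") else res.atom("CA").coord
    radial = anchor - center
    radial -= np.dot(radial, axis) * axis
    return unit(radial)


def _donor_pbr(structure: ProteinStructure, site: Site) -> PBR:
    """The residue's first side-chain donor half-site."""
    for pbr in make_pbrs(structure[site]):
        if pbr.polarity == "donor" and not pbr.is_backbone_atom:
            return pbr
    raise ValueError(f"no side-chain donor at {site}")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    cos = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if cos > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp = unit(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + cos)


def _orient_fragment(fragment: ProteinStructure, acceptor_site: Site,
                     target_primary: np.ndarray, direction: np.ndarray,
                     scaffold_coords: np.ndarray) -> ProteinStructure:
    """Rigidly place a fragment so its acceptor O sits at ``target_primary``
    with the C=O antecedent along ``direction`` (pointing away from the
    scaffold), choosing the remaining roll angle to maximize clearance."""
    res = fragment[acceptor_site]
    o, c = res.atom("O").coord, res.atom("C").coord
    # map the O->C direction onto +direction, O onto the target point
    R0 = _rotation_between(unit(c - o), unit(direction))
    best = None
    coords = np.array([a.coord for r in fragment.residues for a in r.heavy_atoms()])
    for roll in range(0, 360, 15):
        cr = np.cos(np.radians(roll))
        sr = np.sin(np.radians(roll))
        d = unit(direction)
        K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        Rr = np.eye(3) + sr * K + (1 - cr) * (K @ K)
        R = Rr @ R0
        t = target_primary - R @ o
        moved = coords @ R.T + t
        dists = np.linalg.norm(
            moved[:, None, :] - scaffold_coords[None, :, :], axis=2)
        gap = float(dists.min())
        # prefer orientations that hug the scaffold surface without
        # touching it: many near-contacts make a sizeable interface
        near = int((dists < 6.0).sum()) if gap > 2.3 else -1
        if best is None or (near, gap) > (best[0], best[1]):
            best = (near, gap, R, t)
    _, _, R, t = best
    return fragment.transformed(R, t)


def make_planted_complex(spec: FixtureSpec):
    """Scaffold, antigen and the ground-truth interaction list.

    The scaffold is an ideal helix with donor residues (default SER) on one
    face; for each planted bond one short antigen peptide (default ALA
    pentapeptide, its own chain) is placed so that the middle residue's
    backbone carbonyl O sits exactly at the donor's primary point with the
    C=O bond along the donor axis — an ideal, linear hydrogen bond.  The
    remaining roll degree of freedom is chosen so the fragment hugs the
    scaffold surface without touching it, giving the pose a realistic
    interface size.  With
    ``geometric_noise`` > 0 each fragment is displaced by that amount in a
    seeded random direction.  The antigen as a whole is finally moved by a
    seeded rigid motion, so recovering the planted pose genuinely exercises
    the superposition step.

    Returns ``(scaffold, antigen, expected_interactions)`` where each
    expected interaction is ``((scaffold_site, donor_atom), (antigen_site,
    "O"))``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_planted_bonds
    donors = list(spec.donor_types or ["SER"] * n)
    acceptors = list(spec.acceptor_types or ["ALA"] * n)
    if len(donors) != n or len(acceptors) != n:
        raise ValueError("donor/acceptor type lists must match n_planted_bonds")

    sites = _FACE_POSITIONS[:n]
    length = (max(sites) + 2) if n else 12
    one_letter = {v: k for k, v in AA_1TO3.items()}
    seq = ["A"] * length
    for site, aa in zip(sites, donors):
        seq[site - 1] = one_letter[aa]
    library = load_library()
    scaffold = make_ideal_helix("".join(seq), library=library)

    # choose, per donor site, the rotamer whose donor axis points outward
    choice = {}
    for site in sites:
        best = None
        aa = scaffold[("A", site)].aa_type
        for idx in range(len(library[aa])):
            trial = make_ideal_helix("".join(seq), library=library,
                                     rotamer_choice={site - 1: idx})
            pbr = _donor_pbr(trial, ("A", site))
            score = float(np.dot(unit(pbr.primary - pbr.pbr_atom.coord),
                                 _outward(trial, ("A", site))))
            if best is None or score > best[0] + 1e-9:
                best = (score, idx)
        choice[site - 1] = best[1]
    scaffold = make_ideal_helix("".join(seq), library=library,
                                rotamer_choice=choice)

    scaffold_coords = scaffold.heavy_coords()
    fragments: List[ProteinStructure] = []
    expected = []
    for i, (site, acceptor_aa) in enumerate(zip(sites, acceptors)):
        pbr = _donor_pbr(scaffold, ("A", site))
        direction = unit(pbr.primary - pbr.pbr_atom.coord)
        chain_id = chr(ord("B") + i)
        letter = one_letter[acceptor_aa]
        fragment = _build_chain(letter * 5, chain_id, -140.0, 135.0,
                                library=library)
        acceptor_site = (chain_id, 3)
        fragment = _orient_fragment(fragment, acceptor_site, pbr.primary,
                                    direction, scaffold_coords)
        if spec.geometric_noise > 0:
            shift = rng.normal(size=3)
            fragment = fragment.transformed(
                np.eye(3), spec.geometric_noise * unit(shift))
        fragments.append(fragment)
        expected.append(((("A", site), pbr.atom_name), (acceptor_site, "O")))

    if fragments:
        residues = [r for f in fragments for r in f.residues]
        antigen = ProteinStructure([r.copy() for r in residues],
                                   source="planted-fragments")
    else:
        antigen = _build_chain("AAA", "B", -140.0, 135.0, library=library)

    # seeded global rigid motion: docking must recover the planted placement
    from scipy.spatial.transform import Rotation as _Rot
    R = _Rot.random(rng=rng).as_matrix()
    t = rng.uniform(-1, 1, size=3) * 5.0 + np.array([40.0, 0.0, 0.0])
    antigen = antigen.transformed(R, t)
    return scaffold, antigen, expected
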