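"""Side-chain rotamer library and fixed-backbone rotamer placement.

Rotamers are discrete chi-angle combinations read from a plain-text table
(bundled backbone-independent modes by default; a user table in the same
format can be substituted).  Side chains are built by superposing an ideal
residue template (from the chemical component dictionary shipped with
biotite) onto the site's N/CA/C frame and then driving each chi dihedral to
the requested value, so backbone atoms are never moved.  Placed side chains
carry their polar hydrogens, named CHARMM-style.
"""
from __future__ import annotations

import dataclasses
import functools
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bstinfo

from .geometry import dihedral_deg, place_internal, rotate_about_bond, superpose_points, unit
from .structure import Atom, ProteinStructure, Residue, Site, STANDARD_AA

#: chi dihedral atom quadruples, in order chi1..chi4.
CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "ALA": [], "GLY": [], "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

#: polar side-chain hydrogens kept on placed rotamers (CHARMM names).
POLAR_SIDECHAIN_H = {
    "SER": ["HG1"], "THR": ["HG1"], "TYR": ["HH"], "CYS": ["HG1"],
    "ASN": ["HD21", "HD22"], "GLN": ["HE21", "HE22"],
    "ARG": ["HE", "HH11", "HH12", "HH21", "HH22"],
    "LYS": ["HZ1", "HZ2", "HZ3"], "HIS": ["HD1"], "TRP": ["HE1"],
}

# template (CCD) hydrogen names -> CHARMM names, per residue
_H_RENAME = {
    "SER": {"HG": "HG1"}, "CYS": {"HG": "HG1"},
    "LYS": {"HZ1": "HZ1", "HZ2": "HZ2", "HZ3": "HZ3"},
}


def n_chi(aa_type: str) -> int:
    return len(CHI_ATOMS[aa_type])


@dataclasses.dataclass(frozen=True)
class Rotamer:
    aa_type: str
    chi: Tuple[float, ...]
    weight: float = 1.0
    provenance: str = "builtin"

    def __post_init__(self):
        if len(self.chi) != n_chi(self.aa_type):
            raise ValueError(
                f"{self.aa_type} needs {n_chi(self.aa_type)} chi angles, "
                f"got {len(self.chi)}")
        for a in self.chi:
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"chi angle {a} outside (-180, 180]")


@dataclasses.dataclass
class PlacedRotamer:
    """A side chain built onto a fixed backbone site."""

    residue_site: Site
    aa_type: str
    rotamer: Rotamer
    atoms: List[Atom]  # CB onwards, plus polar hydrogens
    backbone: List[Atom] = dataclasses.field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        for a in self.backbone:
            if a.name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if a.is_heavy]


def load_library(source=None) -> Dict[str, List[Rotamer]]:
    """Load a chi-angle rotamer table.

    ``source`` is a path to a table in the bundled plain-text format
    (``AA chi1 chi2 chi3 chi4 weight``); by default the packaged
    backbone-independent table is used.  Rows are kept in file order
    (most probable first).
    """
    if source is None:
        text = (resources.files("hbdock") / "data" / "rotamer_chi.txt").read_text()
        tag = "builtin"
    else:
        text = Path(source).read_text()
        tag = str(source)
    library: Dict[str, List[Rotamer]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        aa = fields[0].upper()
        if aa not in CHI_ATOMS:
            raise ValueError(f"line {lineno}: unknown amino acid {aa!r}")
        try:
            chi = tuple(float(f) for f in fields[1:5] if f != "-")
            weight = float(fields[5])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        try:
            library.setdefault(aa, []).append(
                Rotamer(aa, chi, weight, provenance=tag))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    missing = sorted(STANDARD_AA - set(library))
    if missing:
        raise ValueError(f"rotamer table lacks amino acids: {missing}")
    return library


@functools.lru_cache(maxsize=None)
def _template(aa_type: str):
    """Ideal-geometry template: names, elements, coords, and bond graph."""
    res = bstinfo.residue(aa_type)
    keep = np.ones(len(res), dtype=bool)
    rename = _H_RENAME.get(aa_type, {})
    names = list(res.atom_name)
    for i, (name, elem) in enumerate(zip(res.atom_name, res.element)):
        if name in ("OXT", "HXT", "H2", "H"):
            keep[i] = False
        elif elem == "H":
            new = rename.get(name, name)
            if new in POLAR_SIDECHAIN_H.get(aa_type, []):
                names[i] = new
            else:
                keep[i] = False
    bonds = {i: set() for i in range(len(res))}
    for i, j, _ in res.bonds.as_array():
        bonds[int(i)].add(int(j))
        bonds[int(j)].add(int(i))
    return res, np.array(names), keep, bonds


def _moved_set(names: Sequence[str], bonds, b_name: str, c_name: str):
    """Indices of atoms on the ``c`` side of bond b-c (the atoms a chi
    rotation moves), found by graph traversal."""
    idx = {n: i for i, n in enumerate(names)}
    b, c = idx[b_name], idx[c_name]
    seen = {b, c}
    stack = [c]
    moved = set()
    while stack:
        cur = stack.pop()
        for nb in bonds[cur]:
            if nb not in seen:
                seen.add(nb)
                moved.add(nb)
                stack.append(nb)
    return sorted(moved)


def place_rotamer(structure: ProteinStructure, site: Site, rotamer: Rotamer) -> PlacedRotamer:
    """Build ``rotamer``'s side chain onto the backbone at ``site``.

    The site's N/CA/C atoms define the frame; CB is rebuilt at ideal
    tetrahedral geometry (so GLY sites accept any rotamer).  Backbone
    coordinates are untouched.
    """
    res = structure[site]
    for needed in ("N", "CA", "C"):
        if not res.has_atom(needed):
            raise ValueError(f"site {site} lacks backbone atom {needed}")
    aa = rotamer.aa_type
    tmpl, names, keep, bonds = _template(aa)
    coords = tmpl.coord.astype(float).copy()

    # superpose template backbone onto the site backbone
    name_idx = {n: i for i, n in enumerate(names)}
    tmpl_bb = np.array([coords[name_idx[n]] for n in ("N", "CA", "C")])
    site_bb = np.array([res.atom(n).coord for n in ("N", "CA", "C")])
    R, t, _ = superpose_points(site_bb, tmpl_bb)
    coords = coords @ R.T + t

    site_coord = {n: res.atom(n).coord for n in ("N", "CA", "C")}

    def get(n: str) -> np.ndarray:
        # chi quadruples must use the real backbone frame, not the template's
        return site_coord[n] if n in site_coord else coords[name_idx[n]]

    # drive each chi angle to its target
    for (a, b, c, d), target in zip(CHI_ATOMS[aa], rotamer.chi):
        quad = [get(n) for n in (a, b, c, d)]
        current = dihedral_deg(*quad)
        moved = _moved_set(names, bonds, b, c)
        rot_coords = rotate_about_bond(coords[moved], get(b), get(c),
                                       target - current)
        coords[moved] = rot_coords

    # anti hydroxyl proton for determinism (SER/THR/TYR/CYS)
    hydroxyl = {"SER": ("CA", "CB", "OG", "HG1", 0.96, 109.47),
                "THR": ("CA", "CB", "OG1", "HG1", 0.96, 109.47),
                "TYR": ("CE1", "CZ", "OH", "HH", 0.96, 109.47),
                "CYS": ("CA", "CB", "SG", "HG1", 1.34, 96.0)}
    if aa in hydroxyl:
        a, b, c, h, bond, ang = hydroxyl[aa]
        if h in name_idx:
            coords[name_idx[h]] = place_internal(
                coords[name_idx[a]], coords[name_idx[b]], coords[name_idx[c]],
                bond, ang, 180.0)

    backbone_tmpl = {"N", "CA", "C", "O"}
    atoms = [
        Atom(str(n), str(tmpl.element[i]), coords[i])
        for i, n in enumerate(names)
        if keep[i] and n not in backbone_tmpl
    ]
    backbone = [res.atom(n).copy() for n in ("N", "CA", "C") ]
    return PlacedRotamer(tuple(site), aa, rotamer, atoms, backbone)


def measure_chi(atoms_lookup, aa_type: str) -> Tuple[float, ...]:
    """Chi angles of a residue or placed rotamer (``atoms_lookup`` must
    provide ``atom(name)``)."""
    out = []
    for a, b, c, d in CHI_ATOMS[aa_type]:
        out.append(dihedral_deg(*(atoms_lookup.atom(n).coord for n in (a, b, c, d))))
    return tuple(out)


def install_rotamer(structure: ProteinStructure, placed: PlacedRotamer) -> None:
    """Replace the side chain at the placed rotamer's site, in place.

    Backbone atoms (including amide/terminal hydrogens) are retained from the
    existing residue; every side-chain atom is replaced.
    """
    res = structure[placed.residue_site]
    backbone = [a.copy() for a in res.atoms if a.is_backbone]
    new_res = Residue(res.chain_id, res.res_seq, placed.aa_type,
                      backbone + [a.copy() for a in placed.atoms])
    structure.replace_residue(new_res)


def sidechain_rmsd(a: PlacedRotamer, b: PlacedRotamer) -> float:
    """Heavy-atom RMSD between two placed side chains of the same type."""
    names = sorted(x.name for x in a.heavy_atoms())
    pa = np.array([a.atom(n).coord for n in names])
    pb = np.array([b.atom(n).coord for n in names])
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def select_diverse(rotamers: Sequence[Rotamer], structure: ProteinStructure,
                   site: Site, k: int = 5) -> List[Rotamer]:
    """Pick up to ``k`` structurally diverse rotamers for a site.

    Greedy farthest-point selection on side-chain heavy-atom RMSD after
    placement at the site, seeded with the library's first (most probable)
    rotamer.  Deterministic; returns all rotamers when fewer than ``k`` are
    available.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not rotamers:
        raise ValueError("no rotamers supplied")
    if len(rotamers) <= k:
        return list(rotamers)
    placed = [place_rotamer(structure, site, r) for r in rotamers]
    chosen = [0]
    while len(chosen) < k:
        best_i, best_d = None, -1.0
        for i in range(len(rotamers)):
            if i in chosen:
                continue
            d = min(sidechain_rmsd(placed[i], placed[j]) for j in chosen)
            if d > best_d + 1e-12:
                best_i, best_d = i, d
        chosen.append(best_i)
    return [rotamers[i] for i in sorted(chosen)]
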