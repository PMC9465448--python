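"""Hydrogen-bond half-sites and interaction predicates.

A scaffold half-site (:class:`PBR`, paratope binding region) is a polar atom
(a donatable hydrogen or an acceptor) together with two constructed spatial
points: the *primary* point, the ideal position of the partner atom, 1.25 A
from the half-site atom along the ray from its antecedent through the atom,
and the *secondary* point 1 A further along the same ray, which encodes the
bond's orientation.  An epitope half-site (:class:`EBA`, epitope binding
atom) is the polar atom itself (primary) plus its antecedent position
(secondary).  The registry of polar atoms and antecedents covers backbone
amide/carbonyl groups of every residue, chain termini, and the donor and
acceptor groups of the polar side chains; midpoint antecedents (e.g. the
SER OG lone-pair direction from the HG1/CB midpoint) are supported.

Also here: the geometric hydrogen-bond validity test (acceptor-H distance
< 2.5 A and acceptor-H-donor angle > 120 deg), a salt-bridge test
(carboxylate O within 4.0 A of a charged N) and the nonpolar-contact test
(C/S pair closer than 4.5 A).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import angle_deg, unit
from .rotamers import PlacedRotamer
from .structure import Atom, ProteinStructure, Residue, Site

PRIMARY_OFFSET = 1.25  # A, half-site atom -> primary point
SECONDARY_OFFSET = 1.0  # A, primary -> secondary point

HBOND_MAX_DIST = 2.5  # A, acceptor-hydrogen
HBOND_MIN_ANGLE = 120.0  # deg, acceptor-hydrogen-donor
SALT_BRIDGE_MAX_DIST = 4.0  # A, carboxylate O - charged N
NONPOLAR_MAX_DIST = 4.5  # A, C/S - C/S

Antecedent = Union[str, Tuple[str, str, str]]  # name, or ("midpoint", a, b)

#: side-chain polar atoms and their antecedents, per amino acid.
SIDECHAIN_POLAR: Dict[str, List[Tuple[str, Antecedent]]] = {
    "ARG": [("HE", "NE"), ("HH11", "NH1"), ("HH12", "NH1"),
            ("HH21", "NH2"), ("HH22", "NH2")],
    "LYS": [("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    "ASP": [("OD1", "CG"), ("OD2", "CG")],
    "GLU": [("OE1", "CD"), ("OE2", "CD")],
    "SER": [("HG1", "OG"), ("OG", ("midpoint", "HG1", "CB"))],
    "THR": [("HG1", "OG1"), ("OG1", ("midpoint", "HG1", "CB"))],
    "TYR": [("HH", "OH"), ("OH", ("midpoint", "HH", "CZ"))],
    "ASN": [("OD1", "CG"), ("HD21", "ND2"), ("HD22", "ND2")],
    "GLN": [("OE1", "CD"), ("HE21", "NE2"), ("HE22", "NE2")],
    "HIS": [("HD1", "ND1"), ("NE2", ("midpoint", "CD2", "CE1"))],
    "TRP": [("HE1", "NE1")],
}

#: backbone polar atoms (all residues); terminal rows apply at chain ends.
BACKBONE_POLAR: List[Tuple[str, Antecedent]] = [("O", "C"), ("HN", "N")]
TERMINAL_POLAR: List[Tuple[str, Antecedent]] = [
    ("OT1", "C"), ("OT2", "C"), ("HN1", "N"), ("HN2", "N"), ("HN3", "N"),
]

POSITIVE_AA = {"ARG", "LYS"}
NEGATIVE_AA = {"ASP", "GLU"}

@dataclasses.dataclass(frozen=True, eq=False)
class HalfSite:
    """Geometry shared by PBRs and EBAs."""

    site: Site
    aa_type: str
    atom_name: str
    polarity: str  # donor | acceptor
    charged_class: str  # positive | negative | neutral
    is_backbone_atom: bool


@dataclasses.dataclass(frozen=True, eq=False)
class PBR(HalfSite):
    rotamer_id: Union[int, str]  # index into the site's rotamer set, or "native"
    native_aa: Optional[str] = None  # scaffold's original residue type at the site
    pbr_atom: Atom = None
    antecedent: np.ndarray = None
    primary: np.ndarray = None
    secondary: np.ndarray = None
    donor_heavy: Optional[Atom] = None  # for donor PBRs

    def key(self) -> tuple:
        return (self.site, self.aa_type, str(self.rotamer_id), self.atom_name)

    @property
    def is_design_mutation(self) -> bool:
        return self.native_aa is not None and self.aa_type != self.native_aa


@dataclasses.dataclass(frozen=True, eq=False)
class EBA(HalfSite):
    primary_atom: Atom = None
    secondary: np.ndarray = None
    donor_heavy: Optional[Atom] = None

    @property
    def primary(self) -> np.ndarray:
        return self.primary_atom.coord

    def key(self) -> tuple:
        return (self.site, self.atom_name)


class _AtomView:
    """Uniform atom access over a Residue or a PlacedRotamer (+ backbone)."""

    def __init__(self, obj: Union[Residue, PlacedRotamer]):
        self._obj = obj

    def get(self, name: str) -> Optional[Atom]:
        try:
            return self._obj.atom(name)
        except KeyError:
            return None


def _polar_rows(aa_type: str, view: _AtomView, include_backbone: bool):
    rows = []
    if include_backbone:
        rows.extend(BACKBONE_POLAR)
        rows.extend(
            (name, ant) for name, ant in TERMINAL_POLAR
            if view.get(name) is not None)
    rows.extend(SIDECHAIN_POLAR.get(aa_type, []))
    return rows


def _antecedent_coord(ant: Antecedent, view: _AtomView) -> Optional[np.ndarray]:
    if isinstance(ant, tuple):
        _, a, b = ant
        pa, pb = view.get(a), view.get(b)
        if pa is None or pb is None:
            return None
        return 0.5 * (pa.coord + pb.coord)
    atom = view.get(ant)
    return None if atom is None else atom.coord


def _charged_class(aa_type: str, backbone: bool) -> str:
    if backbone:
        return "neutral"
    if aa_type in POSITIVE_AA:
        return "positive"
    if aa_type in NEGATIVE_AA:
        return "negative"
    return "neutral"


def _donor_heavy_atom(atom_name: str, ant: Antecedent, view: _AtomView) -> Optional[Atom]:
    """Heavy atom covalently carrying a donatable hydrogen."""
    if isinstance(ant, tuple):
        return None
    return view.get(ant)


def make_pbrs(source: Union[Residue, PlacedRotamer],
              site: Optional[Site] = None,
              rotamer_id: Union[int, str] = "native",
              include_backbone: bool = True,
              native_aa: Optional[str] = None) -> List[PBR]:
    """Construct every applicable PBR for a residue or a placed rotamer.

    For a :class:`PlacedRotamer`, only side-chain half-sites are produced
    (the site's backbone half-sites belong to the native residue entry).
    A row whose atom or antecedent is missing is skipped with a warning,
    except hydrogens that are legitimately absent (e.g. PRO ``HN``),
    which are skipped silently.
    """
    if isinstance(source, PlacedRotamer):
        aa = source.aa_type
        res_site = source.residue_site
        include_backbone = False
    else:
        aa = source.aa_type
        res_site = source.site
    if site is None:
        site = res_site
    view = _AtomView(source)
    out: List[PBR] = []
    for atom_name, ant in _polar_rows(aa, view, include_backbone):
        atom = view.get(atom_name)
        if atom is None:
            continue
        ant_coord = _antecedent_coord(ant, view)
        if ant_coord is None:
            warnings.warn(f"{aa} {site}: antecedent {ant!r} for {atom_name} "
                          f"missing; PBR skipped")
            continue
        u = unit(atom.coord - ant_coord)
        primary = atom.coord + PRIMARY_OFFSET * u
        secondary = atom.coord + (PRIMARY_OFFSET + SECONDARY_OFFSET) * u
        is_bb = atom.is_backbone
        polarity = "donor" if atom.is_hydrogen else "acceptor"
        out.append(PBR(
            site=tuple(site), aa_type=aa, atom_name=atom_name,
            polarity=polarity,
            charged_class=_charged_class(aa, is_bb),
            is_backbone_atom=is_bb,
            rotamer_id=rotamer_id, native_aa=native_aa,
            pbr_atom=atom, antecedent=ant_coord,
            primary=primary, secondary=secondary,
            donor_heavy=_donor_heavy_atom(atom_name, ant, view)
            if polarity == "donor" else None,
        ))
    return out


def make_ebas(epitope_residues: Iterable[Residue],
              sasa_map: Dict[Site, float],
              sasa_threshold: float = 0.1) -> List[EBA]:
    """Enumerate epitope half-sites on solvent-exposed residues.

    Residues whose area in ``sasa_map`` does not exceed ``sasa_threshold``
    (A^2) contribute nothing, which keeps buried atoms out of the matching
    stage.
    """
    out: List[EBA] = []
    for res in epitope_residues:
        if sasa_map.get(res.site, 0.0) <= sasa_threshold:
            continue
        view = _AtomView(res)
        for atom_name, ant in _polar_rows(res.aa_type, view, True):
            atom = view.get(atom_name)
            if atom is None:
                continue
            ant_coord = _antecedent_coord(ant, view)
            if ant_coord is None:
                continue
            is_bb = atom.is_backbone
            polarity = "donor" if atom.is_hydrogen else "acceptor"
            out.append(EBA(
                site=res.site, aa_type=res.aa_type, atom_name=atom_name,
                polarity=polarity,
                charged_class=_charged_class(res.aa_type, is_bb),
                is_backbone_atom=is_bb,
                primary_atom=atom, secondary=ant_coord,
                donor_heavy=_donor_heavy_atom(atom_name, ant, view)
                if polarity == "donor" else None,
            ))
    return out


def is_valid_hbond(hydrogen: Atom, donor_heavy: Atom, acceptor: Atom,
                   max_dist: float = HBOND_MAX_DIST,
                   min_angle: float = HBOND_MIN_ANGLE) -> bool:
    """Geometric hydrogen-bond test on realized coordinates."""
    if np.linalg.norm(acceptor.coord - hydrogen.coord) >= max_dist:
        return False
    return angle_deg(acceptor.coord, hydrogen.coord, donor_heavy.coord) > min_angle


_CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CHARGED_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}


def is_salt_bridge(residue_a: Residue, residue_b: Residue,
                   max_dist: float = SALT_BRIDGE_MAX_DIST) -> bool:
    """True when a carboxylate oxygen sits within ``max_dist`` of a charged
    nitrogen (the classic distance criterion for a salt bridge)."""
    if residue_a.aa_type in _CARBOXYLATE_O and residue_b.aa_type in _CHARGED_N:
        acid, base = residue_a, residue_b
    elif residue_b.aa_type in _CARBOXYLATE_O and residue_a.aa_type in _CHARGED_N:
        acid, base = residue_b, residue_a
    else:
        raise ValueError(
            f"salt bridge needs ASP/GLU vs ARG/LYS, got "
            f"{residue_a.aa_type} vs {residue_b.aa_type}")
    for o_name in _CARBOXYLATE_O[acid.aa_type]:
        if not acid.has_atom(o_name):
            continue
        for n_name in _CHARGED_N[base.aa_type]:
            if not base.has_atom(n_name):
                continue
            if np.linalg.norm(acid.atom(o_name).coord
                              - base.atom(n_name).coord) <= max_dist:
                return True
    return False


def salt_bridge_between(placed_atoms: Sequence[Atom], antigen_res: Residue,
                        max_dist: float = SALT_BRIDGE_MAX_DIST) -> bool:
    """Salt-bridge test between placed ASP/GLU side-chain atoms and an
    antigen ARG/LYS residue."""
    if antigen_res.aa_type not in _CHARGED_N:
        return False
    o_coords = [a.coord for a in placed_atoms
                if a.name in ("OD1", "OD2", "OE1", "OE2")]
    n_coords = [antigen_res.atom(n).coord for n in _CHARGED_N[antigen_res.aa_type]
                if antigen_res.has_atom(n)]
    for o in o_coords:
        for n in n_coords:
            if np.linalg.norm(o - n) <= max_dist:
                return True
    return False


def is_nonpolar_contact(candidate_atoms: Sequence[Atom],
                        antigen: Union[ProteinStructure, Sequence[Residue]],
                        max_dist: float = NONPOLAR_MAX_DIST) -> bool:
    """True when any candidate C/S atom lies within ``max_dist`` of an
    antigen C/S atom (strict inequality)."""
    cand = np.array([a.coord for a in candidate_atoms
                     if a.element in ("C", "S")])
    if cand.size == 0:
        return False
    residues = antigen.residues if isinstance(antigen, ProteinStructure) else antigen
    ag = np.array([a.coord for r in residues for a in r.atoms
                   if a.element in ("C", "S")])
    if ag.size == 0:
        return False
    d2 = ((cand[:, None, :] - ag[None, :, :]) ** 2).sum(axis=2)
    return bool((d2 < max_dist ** 2).any())
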