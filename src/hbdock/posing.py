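"""Pose realization and filtering.

A solution group is turned into a three-dimensional pose in stages: the
antigen is rigidly superposed so its epitope half-site atoms meet the
scaffold's ideal partner positions (least-squares, Kabsch); the scaffold
side chains are switched to the group's rotamers (installing any design
mutations); a coarse-grained sphere filter rejects poses with gross overlap
or too small an interface; and an all-atom validation re-checks every
designed hydrogen bond and classifies remaining steric clashes.  Clashes
with mutable paratope residues that do not carry designed bonds survive to
the mutation stage; everything else is fatal.

Steric clash between two residues (heavy atoms only): any pair closer than
1.3 A, more than one pair closer than 1.8 A, or a single sub-1.8 A pair that
involves a backbone atom.  These deliberately loose bounds assume downstream
energy minimization can relax small overlaps.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .geometry import superpose_points
from .hbond import is_valid_hbond
from .matching import SolutionGroup
from .rotamers import PlacedRotamer, install_rotamer
from .structure import Atom, ProteinStructure, Residue, Site

CLASH_HARD = 1.3  # A: any heavy-atom pair below this clashes
CLASH_SOFT = 1.8  # A: >1 pair below this, or 1 pair involving backbone


@dataclasses.dataclass
class FilterConfig:
    clash_hard: float = CLASH_HARD
    clash_soft: float = CLASH_SOFT
    coarse_min_separation: float = 3.39  # A, sphere separation budget
    # Spheres bound heavy-atom *centers*, so two units can be in atomic
    # (van der Waals) contact while their bounding spheres are ~2 carbon
    # radii apart; count a contact when the surface gap is within that
    # distance.
    coarse_contact_pad: float = 4.0  # A
    coarse_min_contacts: int = 12
    coarse_rule: str = "overlap"  # "overlap": reject when overlap exceeds
    # the separation budget; "center": reject when centers are closer than it
    hbond_max_dist: float = 2.5  # A
    hbond_min_angle: float = 120.0  # deg


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclasses.dataclass(frozen=True)
class CoarseSphere:
    owner: Tuple[Site, str]  # (site, "backbone" | "sidechain")
    center: np.ndarray
    radius: float


@dataclasses.dataclass
class ClashRecord:
    scaffold_site: Site
    antigen_site: Site


@dataclasses.dataclass
class Pose:
    group: SolutionGroup
    transform: RigidTransform
    superposition_rmsd: float
    scaffold_state: Optional[ProteinStructure] = None
    antigen_state: Optional[ProteinStructure] = None
    realized_hbonds: List = dataclasses.field(default_factory=list)
    clash_records: List[ClashRecord] = dataclasses.field(default_factory=list)
    mutation_records: List = dataclasses.field(default_factory=list)
    status: str = "pending"  # pending | accepted | rejected
    reject_reason: Optional[str] = None

    def reject(self, reason: str) -> "Pose":
        self.status, self.reject_reason = "rejected", reason
        return self

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def superpose(group: SolutionGroup) -> Tuple[RigidTransform, float]:
    """Optimal rigid placement of the antigen for a solution group.

    Minimizes the RMSD between the epitope half-site primary atoms and the
    scaffold half-sites' primary points.  Requires at least three
    interactions; identical target points are degenerate and an error.
    """
    if len(group) < 3:
        raise ValueError("superposition needs at least 3 interactions")
    fixed = np.array([np.asarray(pbr.primary, float)
                      for pbr, _ in group.interactions])
    moving = np.array([np.asarray(eba.primary, float)
                       for _, eba in group.interactions])
    if np.allclose(fixed.std(axis=0), 0) or np.allclose(moving.std(axis=0), 0):
        raise ValueError("degenerate (coincident) point set")
    R, t, rmsd = superpose_points(fixed, moving)
    return RigidTransform(R, t), rmsd


def clash_atoms(atoms_a: Sequence[Atom], atoms_b: Sequence[Atom],
                hard: float = CLASH_HARD, soft: float = CLASH_SOFT) -> bool:
    """Steric-clash test between two heavy-atom sets."""
    ca = np.array([a.coord for a in atoms_a if a.is_heavy])
    cb = np.array([b.coord for b in atoms_b if b.is_heavy])
    if ca.size == 0 or cb.size == 0:
        return False
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    if (d2 < hard ** 2).any():
        return True
    close = d2 < soft ** 2
    n_close = int(close.sum())
    if n_close > 1:
        return True
    if n_close == 1:
        i, j = np.argwhere(close)[0]
        bb_a = [a for a in atoms_a if a.is_heavy][i].is_backbone
        bb_b = [b for b in atoms_b if b.is_heavy][j].is_backbone
        return bb_a or bb_b
    return False


def detect_clash(residue_a: Residue, residue_b: Residue,
                 hard: float = CLASH_HARD, soft: float = CLASH_SOFT) -> bool:
    """Steric clash between two (non-bonded) residues; hydrogens ignored."""
    return clash_atoms(residue_a.atoms, residue_b.atoms, hard, soft)


def _adjacent(res_a: Residue, res_b: Residue) -> bool:
    return (res_a.chain_id == res_b.chain_id
            and abs(res_a.res_seq - res_b.res_seq) == 1)


def install_design_rotamers(
    scaffold: ProteinStructure,
    group: SolutionGroup,
    placements: Dict[tuple, PlacedRotamer],
    variable_sites: Set[Site],
    config: Optional[FilterConfig] = None,
) -> Tuple[Optional[ProteinStructure], Optional[str]]:
    """Install the group's non-native rotamers into a scaffold copy.

    Returns ``(scaffold_state, None)`` on success or ``(None, reason)`` when
    a newly placed rotamer clashes with another placed rotamer or with a
    residue that cannot be mutated away (anything outside the variable set).
    Clashes with variable non-design residues are tolerated here; the
    mutation stage deals with them.
    """
    cfg = config or FilterConfig()
    state = scaffold.copy()
    design_sites: List[Site] = []
    for site, pbr in sorted(group.rotamer_assignment().items()):
        if pbr.rotamer_id == "native":
            continue
        placed = placements[(site, pbr.aa_type, pbr.rotamer_id)]
        install_rotamer(state, placed)
        design_sites.append(site)
    for site in design_sites:
        new_res = state[site]
        sidechain = new_res.sidechain_atoms(heavy_only=True)
        for other in state.residues:
            if other.site == site:
                continue
            other_atoms = other.heavy_atoms()
            if _adjacent(new_res, other):
                # bonded neighbours: only side-chain/side-chain contacts count
                other_atoms = other.sidechain_atoms(heavy_only=True)
            if clash_atoms(sidechain, other_atoms, cfg.clash_hard, cfg.clash_soft):
                if other.site in design_sites or other.site not in variable_sites:
                    return None, (f"design rotamer at {site} clashes with "
                                  f"{other.aa_type} {other.site}")
    return state, None


def coarse_spheres(structure: ProteinStructure) -> List[CoarseSphere]:
    """Backbone and side-chain bounding spheres for every residue."""
    spheres: List[CoarseSphere] = []
    for res in structure.residues:
        for unit_name, atoms in (("backbone", res.backbone_atoms(heavy_only=True)),
                                 ("sidechain", res.sidechain_atoms(heavy_only=True))):
            if not atoms:
                continue
            coords = np.array([a.coord for a in atoms])
            center = coords.mean(axis=0)
            radius = float(np.linalg.norm(coords - center, axis=1).max())
            spheres.append(CoarseSphere((res.site, unit_name), center, radius))
    return spheres


def coarse_filter(scaffold_state: ProteinStructure,
                  antigen_state: ProteinStructure,
                  config: Optional[FilterConfig] = None) -> Tuple[str, int]:
    """Sphere-level screen of a pose.

    Returns ``("pass", n_contacts)``, ``("coarse_clash", n)`` when any
    scaffold-antigen sphere pair violates the separation rule, or
    ``("small_interface", n)`` when fewer than the minimum number of sphere
    pairs are in contact.
    """
    cfg = config or FilterConfig()
    sa = coarse_spheres(scaffold_state)
    sb = coarse_spheres(antigen_state)
    ca = np.array([s.center for s in sa])
    cb = np.array([s.center for s in sb])
    ra = np.array([s.radius for s in sa])
    rb = np.array([s.radius for s in sb])
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    rsum = ra[:, None] + rb[None, :]
    if cfg.coarse_rule == "center":
        clash = dist < cfg.coarse_min_separation
    else:
        clash = dist < rsum - cfg.coarse_min_separation
    contacts = int((dist <= rsum + cfg.coarse_contact_pad).sum())
    if clash.any():
        return "coarse_clash", contacts
    if contacts < cfg.coarse_min_contacts:
        return "small_interface", contacts
    return "pass", contacts


def validate_pose(pose: Pose, variable_sites: Set[Site],
                  config: Optional[FilterConfig] = None) -> Pose:
    """All-atom validation: designed bonds must form, fatal clashes reject.

    Every designed interaction is re-measured on realized coordinates with
    the hydrogen-bond predicate; one failure rejects the pose.  Scaffold-
    antigen residue clashes reject the pose when they involve a non-variable
    residue, a designed-bond residue, or the backbone of a variable residue;
    clashes confined to side chains of other variable residues are recorded
    for the mutation stage.
    """
    cfg = config or FilterConfig()
    scaffold = pose.scaffold_state
    antigen = pose.antigen_state
    design_bond_sites = {pbr.site for pbr, _ in pose.group.interactions}

    realized = []
    for pbr, eba in pose.group.interactions:
        scaffold_atom = scaffold[pbr.site].atom(pbr.atom_name)
        antigen_res = antigen[eba.site]
        antigen_atom = antigen_res.atom(eba.atom_name)
        if pbr.polarity == "donor":
            donor_heavy = scaffold[pbr.site].atom(_donor_heavy_name(pbr))
            ok = is_valid_hbond(scaffold_atom, donor_heavy, antigen_atom,
                                cfg.hbond_max_dist, cfg.hbond_min_angle)
        else:
            donor_heavy = antigen_res.atom(_donor_heavy_name(eba))
            ok = is_valid_hbond(antigen_atom, donor_heavy, scaffold_atom,
                                cfg.hbond_max_dist, cfg.hbond_min_angle)
        if not ok:
            return pose.reject(f"designed H-bond not realized: "
                               f"{pbr.site}/{pbr.atom_name} - {eba.site}/{eba.atom_name}")
        realized.append((pbr, eba))
    pose.realized_hbonds = realized

    records: List[ClashRecord] = []
    for s_res, a_res in candidate_residue_pairs(scaffold, antigen, cfg.clash_soft):
            if not detect_clash(s_res, a_res, cfg.clash_hard, cfg.clash_soft):
                continue
            if s_res.site not in variable_sites or s_res.site in design_bond_sites:
                return pose.reject(f"steric clash with {s_res.aa_type} {s_res.site}")
            if clash_atoms(s_res.backbone_atoms(heavy_only=True), a_res.atoms,
                           cfg.clash_hard, cfg.clash_soft):
                return pose.reject(f"backbone clash at {s_res.site}")
            records.append(ClashRecord(s_res.site, a_res.site))
    pose.clash_records = records
    pose.status = "validated"
    return pose


def candidate_residue_pairs(a: ProteinStructure, b: ProteinStructure,
                            cutoff: float):
    """Residue pairs whose bounding spheres approach within ``cutoff``."""
    def bounds(st):
        centers, radii = [], []
        for r in st.residues:
            coords = r.heavy_coords()
            c = coords.mean(axis=0)
            centers.append(c)
            radii.append(np.linalg.norm(coords - c, axis=1).max())
        return np.array(centers), np.array(radii)

    ca, ra = bounds(a)
    cb, rb = bounds(b)
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    close = dist <= ra[:, None] + rb[None, :] + cutoff
    for i, j in np.argwhere(close):
        yield a.residues[i], b.residues[j]


def _donor_heavy_name(half_site) -> str:
    if half_site.donor_heavy is None:
        raise ValueError(f"half-site {half_site.atom_name} has no donor heavy atom")
    return half_site.donor_heavy.name
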