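"""Feature-based rescue of clashing variable side chains.

After a pose passes validation it may still carry steric clashes between the
antigen and variable paratope residues that do not form designed bonds.
Each such residue is treated, in ascending residue order, with a strictly
ordered cascade; the first step that yields a clash-free side chain wins:

1. an alternate rotamer of the residue's current amino acid;
2. an ASP rotamer forming a salt bridge with an antigen ARG/LYS (each
   antigen ARG/LYS may partner at most one mutated residue per pose);
3. a GLU rotamer forming such a salt bridge (ASP is preferred as the
   smaller, lower-entropy carboxylate);
4. a polar rotamer making new hydrogen bonds, searched in the order SER,
   THR, ASN, ASP, HIS — at least one bond for SER/THR, two for ASN/ASP/HIS,
   except that an ASN with a single bond to an antigen backbone atom is
   accepted; GLN and GLU are excluded as high-entropy side chains;
5. a nonpolar rotamer (ALA, VAL, LEU, ILE, PHE) making at least one C/S
   contact below 4.5 A; MET, TRP and TYR are excluded;
6. otherwise the pose is rejected as an irreconcilable clash.

Arginine and lysine are never introduced by the cascade.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .hbond import (SIDECHAIN_POLAR, is_nonpolar_contact, is_valid_hbond,
                    salt_bridge_between, make_pbrs)
from .posing import FilterConfig, Pose, clash_atoms, _adjacent
from .rotamers import PlacedRotamer, Rotamer, install_rotamer, place_rotamer
from .structure import ProteinStructure, Residue, Site

SURROUND_RADIUS = 10.0  # A around the site CB; safe superset for clash checks

SALT_BRIDGE_ORDER = ("ASP", "GLU")
POLAR_ORDER = ("SER", "THR", "ASN", "ASP", "HIS")
NONPOLAR_ORDER = ("ALA", "VAL", "LEU", "ILE", "PHE")
FORBIDDEN_TARGETS = {"MET", "TRP", "TYR", "GLN", "LYS", "ARG"}


@dataclasses.dataclass
class MutationRecord:
    site: Site
    from_aa: str
    to_aa: str
    kind: str  # design | clash
    cascade_step: Optional[int]  # 1-5, or None for design mutations
    evidence: str = ""


def _surrounding(scaffold: ProteinStructure, antigen: ProteinStructure,
                 site: Site, radius: float = SURROUND_RADIUS):
    res = scaffold[site]
    anchor = res.atom("CB").coord if res.has_atom("CB") else res.atom("CA").coord
    near_scaffold, near_antigen = [], []
    for st, bucket in ((scaffold, near_scaffold), (antigen, near_antigen)):
        for other in st.residues:
            if st is scaffold and other.site == tuple(site):
                continue
            if np.min(np.linalg.norm(other.heavy_coords() - anchor, axis=1)) <= radius:
                bucket.append(other)
    return near_scaffold, near_antigen


def _clash_free(placed: PlacedRotamer, site_res: Residue,
                near_scaffold: Sequence[Residue],
                near_antigen: Sequence[Residue],
                cfg: FilterConfig) -> bool:
    sidechain = [a for a in placed.atoms if a.is_heavy]
    for other in near_scaffold:
        other_atoms = (other.sidechain_atoms(heavy_only=True)
                       if _adjacent(site_res, other) else other.heavy_atoms())
        if clash_atoms(sidechain, other_atoms, cfg.clash_hard, cfg.clash_soft):
            return False
    for other in near_antigen:
        if clash_atoms(sidechain, other.heavy_atoms(),
                       cfg.clash_hard, cfg.clash_soft):
            return False
    return True


def _antigen_polar_atoms(residues: Sequence[Residue]):
    """(hydrogen, donor-heavy) donors and acceptor atoms, with backbone flags."""
    donors, acceptors = [], []
    for res in residues:
        for hs in make_pbrs(res):  # reuse the polar-atom registry
            if hs.polarity == "donor":
                donors.append((hs.pbr_atom, hs.donor_heavy, hs.is_backbone_atom))
            else:
                acceptors.append((hs.pbr_atom, hs.is_backbone_atom))
    return donors, acceptors


def count_hbonds(placed: PlacedRotamer, antigen_residues: Sequence[Residue],
                 cfg: FilterConfig) -> List[bool]:
    """Valid hydrogen bonds between a placed side chain and the antigen.

    Returns one backbone-partner flag per bond found.
    """
    donors, acceptors = _antigen_polar_atoms(antigen_residues)
    bonds: List[bool] = []
    for hs in make_pbrs(placed):
        if hs.polarity == "donor":
            for acc, acc_bb in acceptors:
                if is_valid_hbond(hs.pbr_atom, hs.donor_heavy, acc,
                                  cfg.hbond_max_dist, cfg.hbond_min_angle):
                    bonds.append(acc_bb)
        else:
            for h, heavy, don_bb in donors:
                if is_valid_hbond(h, heavy, hs.pbr_atom,
                                  cfg.hbond_max_dist, cfg.hbond_min_angle):
                    bonds.append(don_bb)
    return bonds


def step1_repack(site: Site, pose: Pose, library: Dict[str, List[Rotamer]],
                 near_scaffold, near_antigen,
                 cfg: FilterConfig) -> Optional[PlacedRotamer]:
    """First clash-free rotamer of the residue's current amino acid."""
    res = pose.scaffold_state[site]
    for rot in library.get(res.aa_type, []):
        placed = place_rotamer(pose.scaffold_state, site, rot)
        if _clash_free(placed, res, near_scaffold, near_antigen, cfg):
            return placed
    return None


def step2_3_salt_bridge(site: Site, pose: Pose, library,
                        near_scaffold, near_antigen,
                        claimed: Set[Site],
                        cfg: FilterConfig) -> Optional[Tuple[PlacedRotamer, Site, int]]:
    """Clash-free ASP (then GLU) rotamer forming a fresh salt bridge."""
    res = pose.scaffold_state[site]
    charged = [r for r in near_antigen
               if r.aa_type in ("ARG", "LYS") and r.site not in claimed]
    for step, aa in zip((2, 3), SALT_BRIDGE_ORDER):
        for rot in library[aa]:
            placed = place_rotamer(pose.scaffold_state, site, rot)
            if not _clash_free(placed, res, near_scaffold, near_antigen, cfg):
                continue
            for partner in charged:
                if salt_bridge_between(placed.atoms, partner):
                    return placed, partner.site, step
    return None


def step4_polar(site: Site, pose: Pose, library,
                near_scaffold, near_antigen,
                cfg: FilterConfig) -> Optional[Tuple[PlacedRotamer, int]]:
    """Clash-free polar rotamer meeting its minimum hydrogen-bond count."""
    res = pose.scaffold_state[site]
    for aa in POLAR_ORDER:
        minimum = 1 if aa in ("SER", "THR") else 2
        for rot in library[aa]:
            placed = place_rotamer(pose.scaffold_state, site, rot)
            if not _clash_free(placed, res, near_scaffold, near_antigen, cfg):
                continue
            bonds = count_hbonds(placed, near_antigen, cfg)
            if len(bonds) >= minimum:
                return placed, len(bonds)
            if aa == "ASN" and len(bonds) == 1 and bonds[0]:
                return placed, 1  # single bond to antigen backbone
    return None


def step5_nonpolar(site: Site, pose: Pose, library,
                   near_scaffold, near_antigen,
                   cfg: FilterConfig) -> Optional[PlacedRotamer]:
    """Clash-free nonpolar rotamer making at least one C/S contact."""
    res = pose.scaffold_state[site]
    for aa in NONPOLAR_ORDER:
        for rot in library[aa]:
            placed = place_rotamer(pose.scaffold_state, site, rot)
            if not _clash_free(placed, res, near_scaffold, near_antigen, cfg):
                continue
            if is_nonpolar_contact(placed.atoms, near_antigen):
                return placed
    return None


def resolve_clashes(pose: Pose, library: Dict[str, List[Rotamer]],
                    config: Optional[FilterConfig] = None) -> Pose:
    """Run the mutation cascade over every recorded clash site.

    Sites are processed in ascending residue order; earlier resolutions are
    visible to later clash checks.  On success the pose is accepted with its
    mutation records appended; a site no step can fix rejects the pose.
    """
    cfg = config or FilterConfig()
    sites = sorted({tuple(rec.scaffold_site) for rec in pose.clash_records})
    claimed: Set[Site] = set()
    for site in sites:
        scaffold, antigen = pose.scaffold_state, pose.antigen_state
        from_aa = scaffold[site].aa_type
        near_s, near_a = _surrounding(scaffold, antigen, site)

        placed = step1_repack(site, pose, library, near_s, near_a, cfg)
        if placed is not None:
            install_rotamer(scaffold, placed)
            pose.mutation_records.append(MutationRecord(
                site, from_aa, from_aa, "clash", 1, "alternate rotamer"))
            continue

        found = step2_3_salt_bridge(site, pose, library, near_s, near_a,
                                    claimed, cfg)
        if found is not None:
            placed, partner_site, step = found
            claimed.add(partner_site)
            install_rotamer(scaffold, placed)
            pose.mutation_records.append(MutationRecord(
                site, from_aa, placed.aa_type, "clash", step,
                f"salt bridge with antigen {partner_site}"))
            continue

        found = step4_polar(site, pose, library, near_s, near_a, cfg)
        if found is not None:
            placed, n_bonds = found
            install_rotamer(scaffold, placed)
            pose.mutation_records.append(MutationRecord(
                site, from_aa, placed.aa_type, "clash", 4,
                f"{n_bonds} new H-bond(s)"))
            continue

        placed = step5_nonpolar(site, pose, library, near_s, near_a, cfg)
        if placed is not None:
            install_rotamer(scaffold, placed)
            pose.mutation_records.append(MutationRecord(
                site, from_aa, placed.aa_type, "clash", 5, "nonpolar contact"))
            continue

        return pose.reject(f"irreconcilable steric clash at {site}")

    pose.clash_records = []
    pose.status = "accepted"
    return pose
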