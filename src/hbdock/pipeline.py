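"""End-to-end dock-and-mutate pipeline.

``dock`` ties the stages together: polar-hydrogen completion, scaffold
half-site (PBR) generation over native residues plus up to five diverse
rotamers of each polar mutation at every variable site, epitope half-site
(EBA) enumeration on solvent-exposed residues, pairwise geometric matching,
clique expansion into solution groups, pose realization with the full filter
chain, and the clash-mutation cascade.  The core pipeline contains no
randomness: identical inputs and configuration give identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .hbond import EBA, PBR, make_ebas, make_pbrs
from .hydrogens import add_hydrogens
from .matching import MatchConfig, SolutionGroup, enumerate_couples, expand_groups
from .mutation import MutationRecord, resolve_clashes
from .posing import (FilterConfig, Pose, coarse_filter, install_design_rotamers,
                     superpose, validate_pose)
from .rotamers import Rotamer, load_library, place_rotamer, select_diverse
from .sasa import residue_sasa
from .structure import (ProteinStructure, ResidueSelection, Site, merge,
                        resolve_selection, write_pdb)

logger = logging.getLogger("hbdock")

#: amino acids a variable paratope residue may become during pose
#: identification (polar, hydrogen-bond capable; GLN's side chain cannot
#: pair as a scaffold group and is excluded).
DESIGN_ALPHABET = ("ARG", "LYS", "ASP", "GLU", "HIS", "ASN", "TYR",
                   "SER", "THR", "TRP")


@dataclasses.dataclass
class DockConfig:
    match: MatchConfig = dataclasses.field(default_factory=MatchConfig)
    filters: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    sasa_threshold: float = 0.1  # A^2; epitope exposure cut
    max_mutation_rotamers: int = 5


@dataclasses.dataclass
class DockResult:
    scaffold: ProteinStructure
    antigen: ProteinStructure
    pbrs: List[PBR]
    ebas: List[EBA]
    n_couples: int
    groups: List[SolutionGroup]
    poses: List[Pose]
    summary: Dict

    def accepted_poses(self) -> List[Pose]:
        return [p for p in self.poses if p.accepted]


def generate_pbrs(
    scaffold: ProteinStructure,
    paratope: ResidueSelection,
    variable: ResidueSelection,
    library: Dict[str, List[Rotamer]],
    max_rotamers: int = 5,
) -> Tuple[List[PBR], Dict[tuple, object]]:
    """Scaffold half-sites for native residues and candidate mutations.

    Native paratope residues contribute their backbone and side-chain
    half-sites.  Each variable site additionally contributes the side-chain
    half-sites of up to ``max_rotamers`` structurally diverse rotamers of
    every amino acid in the design alphabet.  Returns the half-sites plus a
    registry of the placed rotamers keyed by ``(site, aa, rotamer_index)``.
    """
    pbrs: List[PBR] = []
    placements: Dict[tuple, object] = {}
    for res in scaffold.residues:
        if res.site not in paratope:
            continue
        native_aa = res.aa_type
        pbrs.extend(make_pbrs(res, native_aa=native_aa))
        if res.site not in variable:
            continue
        for aa in DESIGN_ALPHABET:
            rots = select_diverse(library[aa], scaffold, res.site,
                                  k=max_rotamers)
            for idx, rot in enumerate(rots):
                placed = place_rotamer(scaffold, res.site, rot)
                placements[(res.site, aa, idx)] = placed
                pbrs.extend(make_pbrs(placed, rotamer_id=idx,
                                      native_aa=native_aa))
    return pbrs, placements


def dock(
    scaffold: ProteinStructure,
    antigen: ProteinStructure,
    paratope,
    variable,
    epitope,
    config: Optional[DockConfig] = None,
    library: Optional[Dict[str, List[Rotamer]]] = None,
) -> DockResult:
    """Run the full dock-and-mutate pipeline.

    ``paratope``/``variable``/``epitope`` may be selection strings
    (``"A:10-22"``) or iterables of ``(chain, resnum)`` sites; the variable
    set must be a subset of the paratope.  Zero accepted poses is a valid
    outcome.
    """
    cfg = config or DockConfig()
    library = library or load_library()

    scaffold = add_hydrogens(scaffold)
    antigen = add_hydrogens(antigen)

    paratope_sel = resolve_selection(scaffold, paratope, "paratope")
    variable_sel = resolve_selection(scaffold, variable, "variable")
    epitope_sel = resolve_selection(antigen, epitope, "epitope")
    extra = variable_sel.members - paratope_sel.members
    if extra:
        raise ValueError(f"variable residues outside the paratope: {sorted(extra)}")

    pbrs, placements = generate_pbrs(scaffold, paratope_sel, variable_sel,
                                     library, cfg.max_mutation_rotamers)
    sasa_map = residue_sasa(antigen)
    epitope_residues = [r for r in antigen.residues if r.site in epitope_sel]
    ebas = make_ebas(epitope_residues, sasa_map, cfg.sasa_threshold)
    logger.info("half-sites: %d scaffold (PBR), %d epitope (EBA)",
                len(pbrs), len(ebas))

    couples = enumerate_couples(pbrs, ebas, cfg.match)
    groups = expand_groups(couples, cfg.match)
    logger.info("matching: %d couples -> %d solution groups",
                len(couples), len(groups))

    poses: List[Pose] = []
    counts = {"install_clash": 0, "coarse_clash": 0, "small_interface": 0,
              "hbond_failed": 0, "fatal_clash": 0, "irreconcilable_clash": 0,
              "accepted": 0}
    for group in groups:
        transform, rmsd = superpose(group)
        pose = Pose(group, transform, rmsd)
        state, reason = install_design_rotamers(
            scaffold, group, placements, variable_sel.members, cfg.filters)
        if state is None:
            counts["install_clash"] += 1
            poses.append(pose.reject(reason))
            continue
        pose.scaffold_state = state
        pose.antigen_state = antigen.transformed(transform.rotation,
                                                 transform.translation)
        verdict, n_contacts = coarse_filter(pose.scaffold_state,
                                            pose.antigen_state, cfg.filters)
        if verdict != "pass":
            counts[verdict] += 1
            poses.append(pose.reject(verdict))
            continue
        pose = validate_pose(pose, variable_sel.members, cfg.filters)
        if pose.status == "rejected":
            key = ("hbond_failed" if "H-bond" in pose.reject_reason
                   else "fatal_clash")
            counts[key] += 1
            poses.append(pose)
            continue
        for site, to_aa in sorted(pose.group.design_mutations.items()):
            pose.mutation_records.append(MutationRecord(
                site, scaffold[site].aa_type, to_aa, "design", None,
                "matched rotamer"))
        pose = resolve_clashes(pose, library, cfg.filters)
        if pose.status == "rejected":
            counts["irreconcilable_clash"] += 1
        else:
            counts["accepted"] += 1
        poses.append(pose)
        logger.debug("group of %d -> %s (%s)", len(group), pose.status,
                     pose.reject_reason or "ok")

    summary = _summarize(pbrs, ebas, len(couples), groups, poses, counts)
    return DockResult(scaffold, antigen, pbrs, ebas, len(couples), groups,
                      poses, summary)


def _summarize(pbrs, ebas, n_couples, groups, poses, counts) -> Dict:
    accepted = [p for p in poses if p.accepted]
    design_hist = {str(k): 0 for k in range(4)}
    any_clash = 0
    for pose in accepted:
        n_design = len(pose.group.design_mutations)
        design_hist[str(min(n_design, 3))] += 1
        if any(rec.kind == "clash" for rec in pose.mutation_records):
            any_clash += 1
    return {
        "n_pbrs": len(pbrs),
        "n_ebas": len(ebas),
        "n_couples": n_couples,
        "n_groups": len(groups),
        "poses_examined": len(poses),
        "rejections": {k: v for k, v in counts.items() if k != "accepted"},
        "poses_accepted": counts["accepted"],
        "design_mutation_histogram": design_hist,
        "poses_with_clash_mutations": any_clash,
    }


def write_outputs(result: DockResult, out_dir) -> None:
    """Write accepted pose PDBs, the mutation table and the run summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pose in enumerate(result.accepted_poses()):
        remarks = [f"pose {i}: {len(pose.group)} designed H-bonds, "
                   f"superposition RMSD {pose.superposition_rmsd:.3f} A"]
        for pbr, eba in pose.group.interactions:
            remarks.append(f"H-BOND {pbr.site[0]}:{pbr.site[1]}/{pbr.atom_name}"
                           f" -- {eba.site[0]}:{eba.site[1]}/{eba.atom_name}")
        for rec in pose.mutation_records:
            step = rec.cascade_step if rec.cascade_step is not None else "-"
            remarks.append(f"MUTATION {rec.site[0]}:{rec.site[1]} "
                           f"{rec.from_aa}->{rec.to_aa} ({rec.kind}, step {step})")
        combined = merge(pose.scaffold_state, pose.antigen_state)
        write_pdb(combined, out_dir / f"pose_{i:04d}.pdb", remarks=remarks)
        for rec in pose.mutation_records:
            rows.append({
                "pose_id": i, "chain": rec.site[0], "res_seq": rec.site[1],
                "from_aa": rec.from_aa, "to_aa": rec.to_aa, "kind": rec.kind,
                "step": rec.cascade_step if rec.cascade_step is not None else "",
                "evidence": rec.evidence,
            })
    pd.DataFrame(rows, columns=["pose_id", "chain", "res_seq", "from_aa",
                                "to_aa", "kind", "step", "evidence"]
                 ).to_csv(out_dir / "mutations.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
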