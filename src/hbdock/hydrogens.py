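"""Placement of polar hydrogens at ideal covalent geometry.

Only hydrogens that can participate in hydrogen bonds are built: the
backbone amide H (``HN``; ``HN1``-``HN3`` at N-termini), side-chain amide,
guanidinium, ammonium, imidazole, indole and hydroxyl protons.  Bond lengths
are 1.0 A for N-H and 0.96 A for O-H.  Rotatable hydroxyl hydrogens (SER,
THR, TYR) default to the anti conformation about the C-O bond, which keeps
placement deterministic.  Histidine is protonated on ND1, leaving NE2 as an
acceptor.  Existing hydrogens are never moved, and heavy atoms are never
touched, so the operation is idempotent.
"""
from __future__ import annotations

import warnings
from typing import List

import numpy as np

from .geometry import place_internal, unit
from .structure import Atom, ProteinStructure, Residue

NH = 1.00
OH = 0.96
TETRA = 109.47
SP2 = 120.0


def _bisector_h(res: Residue, h_name: str, x: str, a: str, b: str,
                length: float = NH) -> Atom:
    """H on sp2 centre ``x``, in the a-x-b plane, opposite the bisector."""
    xc = res.atom(x).coord
    d = unit(unit(xc - res.atom(a).coord) + unit(xc - res.atom(b).coord))
    return Atom(h_name, "H", xc + length * d)


def _internal_h(res: Residue, h_name: str, refs, bond, angle, dihedral) -> Atom:
    a, b, c = (res.atom(n).coord for n in refs)
    return Atom(h_name, "H", place_internal(a, b, c, bond, angle, dihedral))


def _sidechain_hydrogens(res: Residue) -> List[Atom]:
    aa = res.aa_type
    out: List[Atom] = []

    def need(*names) -> bool:
        return all(res.has_atom(n) for n in names)

    def missing(h) -> bool:
        return not res.has_atom(h)

    if aa == "SER" and need("CA", "CB", "OG") and missing("HG1"):
        out.append(_internal_h(res, "HG1", ("CA", "CB", "OG"), OH, TETRA, 180.0))
    elif aa == "THR" and need("CA", "CB", "OG1") and missing("HG1"):
        out.append(_internal_h(res, "HG1", ("CA", "CB", "OG1"), OH, TETRA, 180.0))
    elif aa == "TYR" and need("CE1", "CZ", "OH") and missing("HH"):
        out.append(_internal_h(res, "HH", ("CE1", "CZ", "OH"), OH, TETRA, 180.0))
    elif aa == "CYS" and need("CA", "CB", "SG") and missing("HG1"):
        out.append(_internal_h(res, "HG1", ("CA", "CB", "SG"), 1.34, 96.0, 180.0))
    elif aa == "ASN" and need("OD1", "CG", "ND2"):
        if missing("HD21"):
            out.append(_internal_h(res, "HD21", ("OD1", "CG", "ND2"), NH, SP2, 180.0))
        if missing("HD22"):
            out.append(_internal_h(res, "HD22", ("OD1", "CG", "ND2"), NH, SP2, 0.0))
    elif aa == "GLN" and need("OE1", "CD", "NE2"):
        if missing("HE21"):
            out.append(_internal_h(res, "HE21", ("OE1", "CD", "NE2"), NH, SP2, 180.0))
        if missing("HE22"):
            out.append(_internal_h(res, "HE22", ("OE1", "CD", "NE2"), NH, SP2, 0.0))
    elif aa == "ARG":
        if need("CD", "NE", "CZ") and missing("HE"):
            out.append(_bisector_h(res, "HE", "NE", "CD", "CZ"))
        if need("NE", "CZ", "NH1"):
            if missing("HH11"):
                out.append(_internal_h(res, "HH11", ("NE", "CZ", "NH1"), NH, SP2, 180.0))
            if missing("HH12"):
                out.append(_internal_h(res, "HH12", ("NE", "CZ", "NH1"), NH, SP2, 0.0))
        if need("NE", "CZ", "NH2"):
            if missing("HH21"):
                out.append(_internal_h(res, "HH21", ("NE", "CZ", "NH2"), NH, SP2, 180.0))
            if missing("HH22"):
                out.append(_internal_h(res, "HH22", ("NE", "CZ", "NH2"), NH, SP2, 0.0))
    elif aa == "LYS" and need("CD", "CE", "NZ"):
        for h_name, chi in (("HZ1", 180.0), ("HZ2", 60.0), ("HZ3", -60.0)):
            if missing(h_name):
                out.append(_internal_h(res, h_name, ("CD", "CE", "NZ"), NH, TETRA, chi))
    elif aa == "HIS":
        # ND1 tautomer: HD1 present, NE2 free to accept
        if need("CG", "CE1", "ND1") and missing("HD1"):
            out.append(_bisector_h(res, "HD1", "ND1", "CG", "CE1"))
    elif aa == "TRP":
        if need("CD1", "CE2", "NE1") and missing("HE1"):
            out.append(_bisector_h(res, "HE1", "NE1", "CD1", "CE2"))
    return out


def _backbone_hydrogens(structure: ProteinStructure, res: Residue) -> List[Atom]:
    out: List[Atom] = []
    if res.aa_type == "PRO":
        return out
    prev = structure.preceding(res)
    if prev is not None:
        if not res.has_atom("HN") and prev.has_atom("C"):
            n = res.atom("N").coord
            d = unit(unit(n - prev.atom("C").coord) + unit(n - res.atom("CA").coord))
            out.append(Atom("HN", "H", n + NH * d))
    else:
        # chain start: protonated amine, three staggered hydrogens
        for h_name, chi in (("HN1", 180.0), ("HN2", 60.0), ("HN3", -60.0)):
            if not res.has_atom(h_name) and not res.has_atom("HN"):
                out.append(_internal_h(res, h_name, ("C", "CA", "N"), NH, TETRA, chi))
    return out


def add_hydrogens(structure: ProteinStructure) -> ProteinStructure:
    """Return a copy of ``structure`` with missing polar hydrogens built.

    Residue types outside the 20 standard amino acids are passed through with
    a warning.  The input is not modified.
    """
    out = structure.copy()
    for res in out.residues:
        try:
            new_atoms = _backbone_hydrogens(out, res) + _sidechain_hydrogens(res)
        except KeyError as exc:
            warnings.warn(f"skipping hydrogens for {res.aa_type} "
                          f"{res.chain_id}:{res.res_seq}: {exc}")
            continue
        res.atoms.extend(new_atoms)
    return out
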