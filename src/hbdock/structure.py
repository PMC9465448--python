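"""Protein structure model and PDB input/output.

The in-memory model is a thin chain/residue/atom hierarchy tailored to
rigid-body docking: coordinates in Angstrom, author residue numbering kept
as-is, atoms addressed by CHARMM-style names (amide hydrogen ``HN``,
C-terminal oxygens ``OT1``/``OT2``).  Parsing and writing of the fixed-column
PDB format is delegated to gemmi; on input, alternate locations are collapsed
to the highest-occupancy conformer and waters/heteroatoms are dropped.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gemmi
import numpy as np

Site = Tuple[str, int]

#: Atom names that belong to the backbone unit of a residue.
BACKBONE_NAMES = {
    "N", "CA", "C", "O", "HN", "OT1", "OT2", "HN1", "HN2", "HN3", "HA",
    "HA1", "HA2",
}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# PDB v3 names -> CHARMM names used internally.
_NAME_TO_CHARMM = {
    "H": "HN", "H1": "HN1", "H2": "HN2", "H3": "HN3", "OXT": "OT2",
}
_SER_CYS_MAP = {"HG": "HG1"}


@dataclasses.dataclass
class Atom:
    """A single atom: CHARMM-style name, element symbol and position (A)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy())


@dataclasses.dataclass
class Residue:
    chain_id: str
    res_seq: int
    aa_type: str
    atoms: List[Atom]

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.chain_id}:{self.res_seq}")

    @property
    def site(self) -> Site:
        return (self.chain_id, self.res_seq)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in {self.aa_type} {self.chain_id}:{self.res_seq}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def backbone_atoms(self, heavy_only: bool = False) -> List[Atom]:
        return [a for a in self.atoms
                if a.is_backbone and (a.is_heavy or not heavy_only)]

    def sidechain_atoms(self, heavy_only: bool = False) -> List[Atom]:
        return [a for a in self.atoms
                if not a.is_backbone and (a.is_heavy or not heavy_only)]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms()])

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.res_seq, self.aa_type,
                       [a.copy() for a in self.atoms])


class ProteinStructure:
    """Ordered collection of residues with unique (chain, residue-number) keys."""

    def __init__(self, residues: Sequence[Residue], source: str = ""):
        self.residues: List[Residue] = list(residues)
        self.source = source
        self._index: Dict[Site, Residue] = {}
        for r in self.residues:
            if r.site in self._index:
                raise ValueError(f"duplicate residue {r.site}")
            self._index[r.site] = r

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __contains__(self, site: Site) -> bool:
        return tuple(site) in self._index

    def __getitem__(self, site: Site) -> Residue:
        return self._index[tuple(site)]

    def chains(self) -> List[str]:
        seen = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain_residues(self, chain_id: str) -> List[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def atoms(self) -> Iterable[Atom]:
        for r in self.residues:
            yield from r.atoms

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for r in self.residues for a in r.heavy_atoms()])

    def copy(self) -> "ProteinStructure":
        return ProteinStructure([r.copy() for r in self.residues], self.source)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a rigidly moved copy: x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for r in out.residues:
            for a in r.atoms:
                a.coord = R @ a.coord + t
        return out

    def replace_residue(self, residue: Residue) -> None:
        """Swap in a residue at an existing site, in place."""
        site = residue.site
        if site not in self._index:
            raise KeyError(f"no residue at {site}")
        idx = next(i for i, r in enumerate(self.residues) if r.site == site)
        self.residues[idx] = residue
        self._index[site] = residue

    def is_chain_start(self, residue: Residue) -> bool:
        """True when no preceding residue is peptide-bonded to this one."""
        prev = self._preceding(residue)
        return prev is None

    def preceding(self, residue: Residue) -> Optional[Residue]:
        return self._preceding(residue)

    def _preceding(self, residue: Residue) -> Optional[Residue]:
        chain = self.chain_residues(residue.chain_id)
        i = next(k for k, r in enumerate(chain) if r.res_seq == residue.res_seq)
        if i == 0:
            return None
        prev = chain[i - 1]
        # a sequence gap breaks the chain even within one chain id
        if prev.has_atom("C") and residue.has_atom("N"):
            if np.linalg.norm(prev.atom("C").coord - residue.atom("N").coord) < 2.0:
                return prev
        return None


@dataclasses.dataclass
class ResidueSelection:
    """A named set of residue sites with a docking role."""

    role: str  # paratope | variable | epitope
    members: Set[Site]

    def __post_init__(self):
        if self.role not in {"paratope", "variable", "epitope"}:
            raise ValueError(f"unknown selection role {self.role!r}")
        self.members = {(c, int(n)) for c, n in self.members}

    def __contains__(self, site: Site) -> bool:
        return tuple(site) in self.members

    def __len__(self) -> int:
        return len(self.members)


def _normalise_name(res_name: str, atom_name: str) -> str:
    name = _NAME_TO_CHARMM.get(atom_name, atom_name)
    if res_name in ("SER", "CYS"):
        name = _SER_CYS_MAP.get(name, name)
    return name


def read_pdb(path, model_index: int = 0) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only standard amino-acid residues are kept; waters and other hetero
    compounds are dropped.  Alternate locations collapse to the conformer of
    highest occupancy.  A residue missing any of its N/CA/C backbone atoms is
    an error.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[model_index]
    residues: List[Residue] = []
    for chain in model:
        for res in chain:
            if res.name not in STANDARD_AA:
                continue
            best: Dict[str, gemmi.Atom] = {}
            for atom in res:
                key = atom.name
                if key not in best or atom.occ > best[key].occ:
                    best[key] = atom
            atoms = [
                Atom(
                    _normalise_name(res.name, a.name),
                    a.element.name if a.element.name else "X",
                    np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for a in best.values()
            ]
            residue = Residue(chain.name, res.seqid.num, res.name, atoms)
            for required in ("N", "CA", "C"):
                if not residue.has_atom(required):
                    raise ValueError(
                        f"{path}: residue {res.name} {chain.name}:{res.seqid.num} "
                        f"is missing backbone atom {required}")
            residues.append(residue)
    if not residues:
        raise ValueError(f"{path}: no amino-acid residues found")
    return ProteinStructure(residues, source=str(path))


def to_gemmi(structure: ProteinStructure, name: str = "hbdock") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_id in structure.chains():
        chain = gemmi.Chain(chain_id)
        for r in structure.chain_residues(chain_id):
            res = gemmi.Residue()
            res.name = r.aa_type
            res.seqid = gemmi.SeqId(r.res_seq, " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: ProteinStructure, path, remarks: Sequence[str] = ()) -> None:
    """Write the structure in fixed-column PDB format.

    ``remarks`` are emitted as ``REMARK 999`` lines before the coordinates.
    """
    st = to_gemmi(structure)
    text = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK 999 {line}\n" for line in remarks)
        text = header + text
    Path(path).write_text(text)


def merge(a: ProteinStructure, b: ProteinStructure) -> ProteinStructure:
    """Combine two structures into one (chain ids must not collide)."""
    shared = set(a.chains()) & set(b.chains())
    if shared:
        raise ValueError(f"chain id collision: {sorted(shared)}")
    return ProteinStructure([r.copy() for r in a.residues] + [r.copy() for r in b.residues],
                            source=f"{a.source}+{b.source}")


def parse_selection(text: str) -> Set[Site]:
    """Parse a selection string ``"A:10-12,B:5"`` into a set of sites."""
    members: Set[Site] = set()
    for token in text.replace(" ", "").split(","):
        if not token:
            continue
        if ":" not in token:
            raise ValueError(f"bad selection token {token!r} (expected CHAIN:NUM)")
        chain, span = token.split(":", 1)
        if "-" in span:
            lo_s, hi_s = span.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(span)
        if hi < lo:
            raise ValueError(f"descending range in token {token!r}")
        for n in range(lo, hi + 1):
            members.add((chain, n))
    return members


def resolve_selection(structure: ProteinStructure, spec_text, role: str) -> ResidueSelection:
    """Resolve a selection string (or iterable of sites) against a structure."""
    if isinstance(spec_text, str):
        members = parse_selection(spec_text)
    else:
        members = {(c, int(n)) for c, n in spec_text}
    missing = sorted(s for s in members if s not in structure)
    if missing:
        raise ValueError(f"{role} selection names absent residues: {missing}")
    return ResidueSelection(role, members)
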