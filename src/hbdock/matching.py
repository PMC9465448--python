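"""Pairwise geometric matching of scaffold and epitope half-sites.

Two half-sites on one protein define a quadrilateral S1-P1-P2-S2 (P =
primary point, S = secondary/antecedent point).  A pair of scaffold
half-sites (PBRs) and a pair of epitope half-sites (EBAs) are *compatible* —
they could be realized simultaneously as two hydrogen bonds by one rigid
placement — when their primary-point distances agree within ``d_limit`` and
the four corresponding quadrilateral angles agree within ``a_limit``
(defaults 1.8 A and 70 deg, thresholds calibrated to admit 85% of the
hydrogen bonds seen in natural antibody-antigen interfaces).

Compatible two-bond couples are expanded into solution groups — sets of
three or more interactions that are pairwise compatible (maximal cliques of
the couple graph) — each group defining one candidate pose together with the
scaffold mutations implied by non-native rotamers.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .hbond import EBA, PBR
from .structure import Site


@dataclasses.dataclass
class MatchConfig:
    d_limit: float = 1.8  # A
    a_limit: float = 70.0  # deg
    min_group_size: int = 3
    max_poses: int = 2000
    #: couples materialized from enumeration, best self-consistency first
    #: (bounds memory on large problems; exact below this size)
    max_couples: int = 200000
    #: couples kept for group expansion (best self-consistency first);
    #: bounds the clique search on large problems
    max_ranked_couples: int = 20000
    #: seed triangles grown into larger groups
    max_grown_triangles: int = 4000
    #: alternative first additions tried per triangle during growth
    growth_branches: int = 4
    #: stop maximal-clique enumeration after this many cliques
    max_maximal_cliques: int = 20000

    def __post_init__(self):
        if min(self.d_limit, self.a_limit) <= 0 or \
           min(self.min_group_size, self.max_poses) <= 0:
            raise ValueError("all matching parameters must be positive")


@dataclasses.dataclass(frozen=True)
class PairGeometry:
    """One distance and the four quadrilateral angles of a half-site pair."""

    D: float
    ang_1p: float
    ang_2p: float
    ang_1s: float
    ang_2s: float


Interaction = Tuple[PBR, EBA]


@dataclasses.dataclass(frozen=True, eq=False)
class Couple:
    """Two interactions that one rigid placement can realize together.

    ``score`` is the couple's worst normalized deviation from perfect
    geometric agreement (|D1-D2|/d_limit and the four angle deviations over
    a_limit): 0 means the two bonds are exactly co-realizable, values close
    to 1 sit at the edge of the tolerance.
    """

    first: Interaction
    second: Interaction
    score: float = 0.0

    @property
    def pbr_pair(self) -> Tuple[PBR, PBR]:
        return (self.first[0], self.second[0])

    @property
    def eba_pair(self) -> Tuple[EBA, EBA]:
        return (self.first[1], self.second[1])

    def interactions(self) -> Tuple[Interaction, Interaction]:
        return (self.first, self.second)


@dataclasses.dataclass(frozen=True, eq=False)
class SolutionGroup:
    """A maximal set of >=3 pairwise-compatible interactions (one pose)."""

    interactions: Tuple[Interaction, ...]
    design_mutations: Dict[Site, str]
    n_positive: int

    def __len__(self) -> int:
        return len(self.interactions)

    def rotamer_assignment(self) -> Dict[Site, PBR]:
        """Site -> representative PBR (carries aa type and rotamer id)."""
        return {pbr.site: pbr for pbr, _ in self.interactions}


def _angles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    un = u / np.linalg.norm(u, axis=1, keepdims=True)
    vn = v / np.linalg.norm(v, axis=1, keepdims=True)
    return np.degrees(np.arccos(np.clip((un * vn).sum(axis=1), -1.0, 1.0)))


def _quad_geometry(P1, S1, P2, S2) -> np.ndarray:
    """Stacked (D, a1p, a2p, a1s, a2s) for arrays of point quadruples."""
    D = np.linalg.norm(P2 - P1, axis=1)
    if np.any(D < 1e-9):
        raise ValueError("coincident primary points")
    for a, b in ((S1, P1), (S2, P2), (S1, S2)):
        if np.any(np.linalg.norm(a - b, axis=1) < 1e-9):
            raise ValueError("coincident quadrilateral vertices")
    a1p = _angles(S1 - P1, P2 - P1)
    a2p = _angles(S2 - P2, P1 - P2)
    a1s = _angles(P1 - S1, S2 - S1)
    a2s = _angles(P2 - S2, S1 - S2)
    return np.stack([D, a1p, a2p, a1s, a2s], axis=1)


def pair_geometry(half_site_1, half_site_2) -> PairGeometry:
    """Distance and quadrilateral angles for two half-sites of one protein.

    Works for two PBRs or two EBAs; the half-sites must come from distinct
    residues.
    """
    if half_site_1.site == half_site_2.site:
        raise ValueError("half-site pairs must come from distinct residues")
    g = _quad_geometry(
        np.asarray(half_site_1.primary, float)[None, :],
        np.asarray(half_site_1.secondary, float)[None, :],
        np.asarray(half_site_2.primary, float)[None, :],
        np.asarray(half_site_2.secondary, float)[None, :],
    )[0]
    return PairGeometry(*g)


def pairing_allowed(pbr: PBR, eba: EBA) -> bool:
    """Amino-acid/atom-type screen for a single scaffold-epitope pairing.

    A donor must meet an acceptor, and the (scaffold class, antigen class)
    combination must be one of: backbone-anything, non-ARG/LYS/GLN side
    chain-backbone, charge-complementary ARG/LYS-ASP/GLU pairs, or two
    short-to-medium polar side chains (HIS/ASN/ASP/TYR/SER/THR/TRP) with the
    ASN-ASP combination excluded.
    """
    if pbr.polarity == eba.polarity:
        return False
    if pbr.is_backbone_atom:
        return True  # scaffold backbone may bond anything
    if eba.is_backbone_atom:
        return pbr.aa_type not in ("ARG", "LYS", "GLN")
    a, b = pbr.aa_type, eba.aa_type
    if a in ("ARG", "LYS"):
        return b in ("ASP", "GLU")
    if a in ("ASP", "GLU") and b in ("ARG", "LYS"):
        return True
    polar7 = {"HIS", "ASN", "ASP", "TYR", "SER", "THR", "TRP"}
    if a in polar7 and b in polar7:
        return {a, b} != {"ASN", "ASP"}
    return False


def couple_compatible(pbr_pair_geom: PairGeometry, eba_pair_geom: PairGeometry,
                      config: Optional[MatchConfig] = None) -> bool:
    """Distance/angle agreement test between two half-site pair geometries."""
    c = config or MatchConfig()
    return (abs(pbr_pair_geom.D - eba_pair_geom.D) < c.d_limit
            and abs(pbr_pair_geom.ang_1p - eba_pair_geom.ang_1p) < c.a_limit
            and abs(pbr_pair_geom.ang_2p - eba_pair_geom.ang_2p) < c.a_limit
            and abs(pbr_pair_geom.ang_1s - eba_pair_geom.ang_1s) < c.a_limit
            and abs(pbr_pair_geom.ang_2s - eba_pair_geom.ang_2s) < c.a_limit)


def _half_site_pairs(half_sites: Sequence, limit_positive: bool):
    """Index pairs (i < j) from distinct residues, with at most one
    positively charged member when ``limit_positive``; plus geometry rows."""
    n = len(half_sites)
    if n < 2:
        return np.empty((0, 2), int), np.empty((0, 5))
    sites = {}
    site_id = np.array([sites.setdefault(h.site, len(sites)) for h in half_sites])
    ii, jj = np.triu_indices(n, k=1)
    keep = site_id[ii] != site_id[jj]
    if limit_positive:
        pos = np.array([h.charged_class == "positive" for h in half_sites])
        keep &= ~(pos[ii] & pos[jj])
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return np.empty((0, 2), int), np.empty((0, 5))
    P = np.array([np.asarray(h.primary, float) for h in half_sites])
    S = np.array([np.asarray(h.secondary, float) for h in half_sites])
    geom = _quad_geometry(P[ii], S[ii], P[jj], S[jj])
    return np.stack([ii, jj], axis=1), geom


def enumerate_couples(pbrs: Sequence[PBR], ebas: Sequence[EBA],
                      config: Optional[MatchConfig] = None) -> List[Couple]:
    """All compatible two-bond couples between scaffold and epitope.

    A couple is a PBR pair plus an EBA pair (each pair from distinct
    residues, at most one positively charged PBR) under one of the two
    possible assignments, where both individual pairings pass the type
    screen and the pair geometries agree within the distance and angle
    limits.  Output order is deterministic.
    """
    c = config or MatchConfig()
    pairs_p, geom_p = _half_site_pairs(pbrs, limit_positive=True)
    pairs_e, geom_e = _half_site_pairs(ebas, limit_positive=False)
    if len(pairs_p) == 0 or len(pairs_e) == 0:
        return []

    allowed = np.array([[pairing_allowed(p, e) for e in ebas] for p in pbrs],
                       dtype=bool)

    order = np.argsort(geom_p[:, 0], kind="stable")
    pairs_p, geom_p = pairs_p[order], geom_p[order]
    D_sorted = geom_p[:, 0]

    # accumulate (pbr_i, eba_k, pbr_j, eba_l, score) rows, then materialize
    chunks = []
    for (k, l), ge in zip(pairs_e, geom_e):
        lo = np.searchsorted(D_sorted, ge[0] - c.d_limit, side="right")
        hi = np.searchsorted(D_sorted, ge[0] + c.d_limit, side="left")
        if lo >= hi:
            continue
        gp = geom_p[lo:hi]
        pp = pairs_p[lo:hi]
        d_dev = np.abs(gp[:, 0] - ge[0]) / c.d_limit
        # straight assignment: i<->k, j<->l
        ang = np.abs(gp[:, 1:5] - ge[1:5][None, :]) / c.a_limit
        ok = (ang < 1.0).all(axis=1) \
            & allowed[pp[:, 0], k] & allowed[pp[:, 1], l]
        if ok.any():
            dev = np.maximum(d_dev[ok], ang[ok].max(axis=1))
            rows = np.empty((int(ok.sum()), 5))
            rows[:, 0] = pp[ok, 0]
            rows[:, 1] = k
            rows[:, 2] = pp[ok, 1]
            rows[:, 3] = l
            rows[:, 4] = dev
            chunks.append(rows)
        # crossed assignment: i<->l, j<->k (EBA pair traversed as l,k)
        ang = np.abs(gp[:, 1:5] - ge[[2, 1, 4, 3]][None, :]) / c.a_limit
        ok = (ang < 1.0).all(axis=1) \
            & allowed[pp[:, 0], l] & allowed[pp[:, 1], k]
        if ok.any():
            dev = np.maximum(d_dev[ok], ang[ok].max(axis=1))
            rows = np.empty((int(ok.sum()), 5))
            rows[:, 0] = pp[ok, 0]
            rows[:, 1] = l
            rows[:, 2] = pp[ok, 1]
            rows[:, 3] = k
            rows[:, 4] = dev
            chunks.append(rows)
    if not chunks:
        return []
    table = np.concatenate(chunks, axis=0)
    if len(table) > c.max_couples:
        keep = np.argsort(table[:, 4], kind="stable")[: c.max_couples]
        table = table[keep]
    out = [Couple((pbrs[int(i)], ebas[int(k)]), (pbrs[int(j)], ebas[int(l)]),
                  float(sc))
           for i, k, j, l, sc in table]
    out.sort(key=_couple_sort_key)
    return out


def _interaction_key(inter: Interaction):
    pbr, eba = inter
    return pbr.key() + eba.key()


def _couple_sort_key(couple: Couple):
    a, b = sorted((_interaction_key(couple.first), _interaction_key(couple.second)))
    return (a, b)


def _group_from_clique(nodes, node_to_inter) -> SolutionGroup:
    interactions = tuple(node_to_inter[n] for n in sorted(nodes))
    design = {}
    n_positive = 0
    seen_sites = set()
    for pbr, _ in interactions:
        if pbr.site in seen_sites:
            continue
        seen_sites.add(pbr.site)
        if pbr.charged_class == "positive":
            n_positive += 1
        native = getattr(pbr, "native_aa", None)
        if native is not None and pbr.aa_type != native:
            design[pbr.site] = pbr.aa_type
    return SolutionGroup(interactions, design, n_positive)


def expand_groups(couples: Sequence[Couple],
                  config: Optional[MatchConfig] = None) -> List[SolutionGroup]:
    """Expand compatible couples into candidate solution groups.

    Nodes of the compatibility graph are the distinct interactions appearing
    in couples; edges are the couples themselves, weighted by their
    geometric self-consistency score.  Every emitted group is a clique of at
    least ``min_group_size`` interactions.  Two families are produced and
    merged: (a) the graph's maximal cliques, and (b) growth chains — each of
    the best-scoring triangles extended one interaction at a time, always
    adding the candidate with the smallest worst-pair deviation, emitting
    every intermediate size.  The growth chains matter because with the
    deliberately permissive pairwise tolerances a maximal clique often mixes
    one rigidly realizable bond set with geometrically looser bystanders
    that doom the pose at validation; the nested subgroups preserve the
    clean cores as candidates of their own.

    Groups are ranked by worst-pair deviation (best first; ties broken by
    larger size, then lexicographically), and at most ``max_poses`` are
    returned.  Groups with more than one positively charged design residue
    are dropped.  On small inputs (within the ranking bounds) the output is
    a superset of all maximal cliques of size >= ``min_group_size``.
    """
    c = config or MatchConfig()
    ranked = sorted(couples, key=lambda cp: (cp.score, _couple_sort_key(cp)))
    ranked = ranked[: c.max_ranked_couples]

    node_to_inter: Dict[tuple, Interaction] = {}
    edge_score: Dict[Tuple[tuple, tuple], float] = {}
    adjacency: Dict[tuple, set] = {}
    for couple in ranked:
        ka = _interaction_key(couple.first)
        kb = _interaction_key(couple.second)
        node_to_inter.setdefault(ka, couple.first)
        node_to_inter.setdefault(kb, couple.second)
        edge = (ka, kb) if ka < kb else (kb, ka)
        if edge not in edge_score or couple.score < edge_score[edge]:
            edge_score[edge] = couple.score
        adjacency.setdefault(ka, set()).add(kb)
        adjacency.setdefault(kb, set()).add(ka)

    def pair_score(a: tuple, b: tuple) -> float:
        return edge_score[(a, b) if a < b else (b, a)]

    from .geometry import superpose_points

    def group_rmsd(nodes) -> float:
        """Least-squares residual of realizing every bond rigidly at once:
        the direct measure of a group's co-realizability."""
        fixed = np.array([np.asarray(node_to_inter[n][0].primary, float)
                          for n in nodes])
        moving = np.array([np.asarray(node_to_inter[n][1].primary, float)
                           for n in nodes])
        _, _, rmsd = superpose_points(fixed, moving)
        return rmsd

    emitted: Dict[frozenset, float] = {}

    def emit(nodes) -> None:
        key = frozenset(nodes)
        if len(key) >= c.min_group_size and key not in emitted:
            emitted[key] = group_rmsd(sorted(key))

    # (a) maximal cliques (bounded enumeration)
    graph = nx.Graph()
    for node in sorted(node_to_inter):
        graph.add_node(node)
    for (a, b) in sorted(edge_score):
        graph.add_edge(a, b)
    for n_cliques, clique in enumerate(nx.find_cliques(graph)):
        if n_cliques >= c.max_maximal_cliques:
            break
        emit(clique)

    # (b) consistency-first growth chains from the best triangles
    triangles = []
    for (a, b), sc in edge_score.items():
        for d in sorted(adjacency[a] & adjacency[b]):
            tri = frozenset((a, b, d))
            triangles.append((max(sc, pair_score(a, d), pair_score(b, d)),
                              tuple(sorted(tri))))
    triangles = sorted(set(triangles))[: c.max_grown_triangles]

    def residual_of(node, R, t) -> float:
        pbr, eba = node_to_inter[node]
        realized = R @ np.asarray(eba.primary, float) + t
        return float(np.linalg.norm(realized - np.asarray(pbr.primary, float)))

    def grow(seed_members, first_choice_rank=0):
        members = list(seed_members)
        emit(members)
        first_stage = True
        while True:
            candidates = set.intersection(*(adjacency[m] for m in members)) \
                - set(members)
            if not candidates:
                return
            # rigid-consistency-guided growth: superpose the current group's
            # epitope primaries onto the scaffold primaries and admit the
            # candidate whose own bond has the smallest residual under that
            # placement -- co-realizable bonds join before loose bystanders
            fixed = np.array([np.asarray(node_to_inter[m][0].primary, float)
                              for m in members])
            moving = np.array([np.asarray(node_to_inter[m][1].primary, float)
                               for m in members])
            R, t, _ = superpose_points(fixed, moving)
            ranked_cands = sorted(candidates,
                                  key=lambda n: (residual_of(n, R, t), n))
            pick = first_choice_rank if first_stage else 0
            if pick >= len(ranked_cands):
                return
            members.append(ranked_cands[pick])
            first_stage = False
            emit(members)

    for _, tri in triangles:
        # the three-point superposition is the least determined, so branch
        # over the first admitted candidate before growing greedily
        for rank in range(c.growth_branches):
            grow(tri, first_choice_rank=rank)

    # collapse rotamer variants that realize the same physical bonds,
    # preferring the variant with the fewest design mutations
    def physical_key(nodes) -> frozenset:
        out = []
        for n in nodes:
            pbr, eba = node_to_inter[n]
            out.append((pbr.site, pbr.aa_type, pbr.atom_name,
                        eba.site, eba.atom_name))
        return frozenset(out)

    def n_design(nodes) -> int:
        return sum(1 for n in nodes
                   if node_to_inter[n][0].rotamer_id != "native")

    deduped: Dict[frozenset, tuple] = {}
    for key, score in emitted.items():
        pkey = physical_key(key)
        entry = (score, n_design(key), tuple(sorted(key)))
        if pkey not in deduped or entry < deduped[pkey]:
            deduped[pkey] = entry

    groups: List[SolutionGroup] = []
    for score, _, nodes in deduped.values():
        group = _group_from_clique(nodes, node_to_inter)
        if group.n_positive > 1:
            continue
        groups.append((score, group))
    groups.sort(key=lambda pair: (
        round(pair[0], 6), -len(pair[1]),
        tuple(_interaction_key(i) for i in pair[1].interactions)))
    return [g for _, g in groups[: c.max_poses]]
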