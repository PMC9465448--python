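"""Pairwise geometry, couple screening and group expansion, checked against
independent brute-force oracles on small instances."""
import itertools
import math

import numpy as np
import pytest

from hbdock.hbond import EBA, PBR
from hbdock.matching import (Couple, MatchConfig, PairGeometry,
                             couple_compatible, enumerate_couples,
                             expand_groups, pair_geometry, pairing_allowed)
from hbdock.structure import Atom


def make_pbr(site_num, primary, secondary, polarity="donor", aa="SER",
             atom_name="HG1", charged="neutral", backbone=False,
             rotamer_id="native", native_aa=None):
    primary = np.asarray(primary, float)
    secondary = np.asarray(secondary, float)
    atom_coord = primary - 1.25 * (secondary - primary) / np.linalg.norm(secondary - primary)
    element = "H" if polarity == "donor" else "O"
    return PBR(site=("A", site_num), aa_type=aa, atom_name=atom_name,
               polarity=polarity, charged_class=charged,
               is_backbone_atom=backbone, rotamer_id=rotamer_id,
               native_aa=native_aa,
               pbr_atom=Atom(atom_name, element, atom_coord),
               antecedent=atom_coord - (primary - atom_coord),
               primary=primary, secondary=secondary)


def make_eba(site_num, primary, secondary, polarity="acceptor", aa="ALA",
             atom_name="O", backbone=True):
    element = "H" if polarity == "donor" else "O"
    return EBA(site=("X", site_num), aa_type=aa, atom_name=atom_name,
               polarity=polarity, charged_class="neutral",
               is_backbone_atom=backbone,
               primary_atom=Atom(atom_name, element, np.asarray(primary, float)),
               secondary=np.asarray(secondary, float))


class TestPairGeometry:
    def test_rectangle(self):
        a = make_pbr(1, (0, 0, 0), (0, 1, 0))
        b = make_pbr(2, (2, 0, 0), (2, 1, 0))
        g = pair_geometry(a, b)
        assert g.D == pytest.approx(2.0)
        for ang in (g.ang_1p, g.ang_2p, g.ang_1s, g.ang_2s):
            assert ang == pytest.approx(90.0, abs=1e-9)

    def test_collinear_secondary_gives_straight_angle(self):
        a = make_pbr(1, (0, 0, 0), (-1, 0, 0))
        b = make_pbr(2, (2, 0, 0), (2, 1, 0))
        assert pair_geometry(a, b).ang_1p == pytest.approx(180.0)

    def test_same_residue_rejected(self):
        a = make_pbr(1, (0, 0, 0), (0, 1, 0))
        b = make_pbr(1, (2, 0, 0), (2, 1, 0))
        with pytest.raises(ValueError):
            pair_geometry(a, b)

    def test_coincident_points_rejected(self):
        a = make_pbr(1, (0, 0, 0), (0, 1, 0))
        b = make_pbr(2, (1e-12, 0, 0), (0, 1, 0))
        with pytest.raises(ValueError):
            pair_geometry(a, b)

    def test_random_configurations_match_law_of_cosines(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.uniform(-5, 5, size=(4, 3))  # P1 S1 P2 S2
            p1, s1, p2, s2 = pts
            if min(np.linalg.norm(p1 - p2), np.linalg.norm(s1 - p1),
                   np.linalg.norm(s2 - p2)) < 1e-3:
                continue
            g = pair_geometry(make_pbr(1, p1, s1), make_pbr(2, p2, s2))

            def cosine_angle(x, v, w):
                # law of cosines in triangle (v, x, w), angle at x
                a = np.linalg.norm(v - x)
                b = np.linalg.norm(w - x)
                c = np.linalg.norm(v - w)
                return math.degrees(math.acos(
                    max(-1.0, min(1.0, (a * a + b * b - c * c) / (2 * a * b)))))

            assert g.D == pytest.approx(np.linalg.norm(p1 - p2), abs=1e-9)
            assert g.ang_1p == pytest.approx(cosine_angle(p1, s1, p2), abs=1e-6)
            assert g.ang_2p == pytest.approx(cosine_angle(p2, s2, p1), abs=1e-6)
            assert g.ang_1s == pytest.approx(cosine_angle(s1, p1, s2), abs=1e-6)
            assert g.ang_2s == pytest.approx(cosine_angle(s2, p2, s1), abs=1e-6)


class TestCoupleCompatible:
    def test_identical_geometries_compatible(self):
        g = PairGeometry(10.0, 80.0, 95.0, 100.0, 85.0)
        assert couple_compatible(g, g)

    def test_distance_bound(self):
        a = PairGeometry(10.0, 90.0, 90.0, 90.0, 90.0)
        b = PairGeometry(12.0, 90.0, 90.0, 90.0, 90.0)
        assert not couple_compatible(a, b)
        assert couple_compatible(a, PairGeometry(11.7, 90, 90, 90, 90))

    def test_angle_bound(self):
        a = PairGeometry(10.0, 90.0, 90.0, 90.0, 90.0)
        assert not couple_compatible(a, PairGeometry(10.0, 161.0, 90, 90, 90))

    def test_symmetric_under_joint_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            dp, de = rng.uniform(2, 12, size=2)
            ap = rng.uniform(0, 180, size=4)
            ae = rng.uniform(0, 180, size=4)
            a = PairGeometry(dp, *ap)
            b = PairGeometry(de, *ae)
            a_sw = PairGeometry(dp, ap[1], ap[0], ap[3], ap[2])
            b_sw = PairGeometry(de, ae[1], ae[0], ae[3], ae[2])
            assert couple_compatible(a, b) == couple_compatible(a_sw, b_sw)


def _random_instance(rng, n_pbr=6, n_eba=6):
    pbrs, ebas = [], []
    for i in range(n_pbr):
        p = rng.uniform(-8, 8, size=3)
        s = p + rng.normal(size=3)
        polarity = "donor" if rng.random() < 0.5 else "acceptor"
        charged = "positive" if rng.random() < 0.25 else "neutral"
        aa = "LYS" if charged == "positive" else "SER"
        name = ("HZ1" if aa == "LYS" else "HG1") if polarity == "donor" else "OG"
        pbrs.append(make_pbr(i, p, s, polarity=polarity, aa=aa,
                             atom_name=name, charged=charged))
    for i in range(n_eba):
        p = rng.uniform(-8, 8, size=3)
        s = p + rng.normal(size=3)
        polarity = "acceptor" if rng.random() < 0.5 else "donor"
        backbone = rng.random() < 0.7
        aa = "ALA" if backbone else "ASP"
        name = ("O" if polarity == "acceptor" else "HN") if backbone \
            else "OD1"
        ebas.append(make_eba(i, p, s, polarity=polarity, aa=aa,
                             atom_name=name, backbone=backbone))
    return pbrs, ebas


def brute_force_couples(pbrs, ebas, config):
    """Independent enumeration over every pair-of-pairs and assignment."""
    found = set()
    for i, j in itertools.combinations(range(len(pbrs)), 2):
        if pbrs[i].site == pbrs[j].site:
            continue
        if pbrs[i].charged_class == pbrs[j].charged_class == "positive":
            continue
        gp = pair_geometry(pbrs[i], pbrs[j])
        for k, l in itertools.combinations(range(len(ebas)), 2):
            if ebas[k].site == ebas[l].site:
                continue
            ge = pair_geometry(ebas[k], ebas[l])
            ge_swapped = PairGeometry(ge.D, ge.ang_2p, ge.ang_1p,
                                      ge.ang_2s, ge.ang_1s)
            for (ek, el), g in (((k, l), ge), ((l, k), ge_swapped)):
                if not (pairing_allowed(pbrs[i], ebas[ek])
                        and pairing_allowed(pbrs[j], ebas[el])):
                    continue
                if couple_compatible(gp, g, config):
                    found.add(frozenset(((i, ek), (j, el))))
    return found


def _couple_key(couple, pbrs, ebas):
    return frozenset(((pbrs.index(couple.first[0]), ebas.index(couple.first[1])),
                      (pbrs.index(couple.second[0]), ebas.index(couple.second[1]))))


def test_enumerate_couples_equals_brute_force():
    rng = np.random.default_rng(11)
    cfg = MatchConfig()
    for _ in range(25):
        pbrs, ebas = _random_instance(rng)
        got = {_couple_key(c, pbrs, ebas)
               for c in enumerate_couples(pbrs, ebas, cfg)}
        assert got == brute_force_couples(pbrs, ebas, cfg)


def test_double_positive_pbr_pair_excluded():
    # two positive donors in perfect geometric agreement with the EBAs
    p1 = make_pbr(1, (0, 0, 0), (0, 1, 0), aa="LYS", atom_name="HZ1",
                  charged="positive")
    p2 = make_pbr(2, (5, 0, 0), (5, 1, 0), aa="ARG", atom_name="HE",
                  charged="positive")
    e1 = make_eba(1, (0, 0, 0), (0, 1, 0), aa="ASP", atom_name="OD1",
                  backbone=False)
    e2 = make_eba(2, (5, 0, 0), (5, 1, 0), aa="GLU", atom_name="OE1",
                  backbone=False)
    assert enumerate_couples([p1, p2], [e1, e2]) == []
    # replacing one positive with a neutral donor restores the couple
    p2n = make_pbr(2, (5, 0, 0), (5, 1, 0), aa="SER", atom_name="HG1")
    e2b = make_eba(2, (5, 0, 0), (5, 1, 0), aa="ALA", atom_name="O",
                   backbone=True)
    assert len(enumerate_couples([p1, p2n], [e1, e2b])) == 1


def test_planted_match_is_found_exactly():
    # asymmetric vertex angles (170 vs 20 deg) so only one assignment fits
    s1 = np.array([np.cos(np.radians(170)), np.sin(np.radians(170)), 0.0])
    s2 = np.array([6, 0, 0]) + np.array([-np.cos(np.radians(20)),
                                         np.sin(np.radians(20)), 0.0])
    pbrs = [make_pbr(1, (0, 0, 0), s1),
            make_pbr(2, (6, 0, 0), s2),
            make_pbr(3, (40, 40, 40), (40, 41, 40))]  # geometric outlier
    ebas = [make_eba(1, (0, 0, 0), s1),
            make_eba(2, (6, 0, 0), s2)]
    couples = enumerate_couples(pbrs, ebas)
    assert len(couples) == 1
    (pa, ea), (pb, eb) = couples[0].interactions()
    assert {pa.site[1], pb.site[1]} == {1, 2}
    assert couples[0].score == pytest.approx(0.0, abs=1e-9)


def test_monotonicity_in_limits():
    rng = np.random.default_rng(5)
    pbrs, ebas = _random_instance(rng, 8, 8)
    n_narrow = len(enumerate_couples(pbrs, ebas,
                                     MatchConfig(d_limit=0.9, a_limit=35.0)))
    n_default = len(enumerate_couples(pbrs, ebas, MatchConfig()))
    n_wide = len(enumerate_couples(pbrs, ebas,
                                   MatchConfig(d_limit=3.6, a_limit=140.0)))
    assert n_narrow <= n_default <= n_wide


# ---------------------------------------------------------------------------
# group expansion vs maximal-clique oracle

def _abstract_interactions(n):
    """n interactions on n distinct scaffold and epitope residues."""
    out = []
    for i in range(n):
        pbr = make_pbr(i, (float(3 * i), 0, 0), (float(3 * i), 1, 0),
                       native_aa="SER")
        eba = make_eba(i, (float(3 * i), 0, 0), (float(3 * i), 1, 0))
        out.append((pbr, eba))
    return out


def brute_force_maximal_cliques(n, edges, min_size=3):
    cliques = []
    for size in range(min_size, n + 1):
        for combo in itertools.combinations(range(n), size):
            if all(frozenset(p) in edges
                   for p in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


def test_expand_groups_covers_maximal_cliques():
    rng = np.random.default_rng(23)
    for _ in range(30):
        n = int(rng.integers(4, 13))
        inters = _abstract_interactions(n)
        edges = set()
        couples = []
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                edges.add(frozenset((i, j)))
                couples.append(Couple(inters[i], inters[j],
                                      score=float(rng.random())))
        groups = expand_groups(couples, MatchConfig())
        got = [{inters.index(i) for i in g.interactions} for g in groups]
        # every brute-force maximal clique of size >= 3 is emitted
        for clique in brute_force_maximal_cliques(n, edges):
            assert clique in got
        # and everything emitted is a genuine clique of size >= 3
        for members in got:
            assert len(members) >= 3
            for a, b in itertools.combinations(sorted(members), 2):
                assert frozenset((a, b)) in edges


def test_triangle_emitted_and_open_path_not():
    inters = _abstract_interactions(3)
    ab = Couple(inters[0], inters[1], 0.1)
    ac = Couple(inters[0], inters[2], 0.1)
    bc = Couple(inters[1], inters[2], 0.1)
    triangle = expand_groups([ab, ac, bc])
    assert len(triangle) == 1 and len(triangle[0]) == 3
    assert expand_groups([ab, ac]) == []  # BC missing: no group of size 3


def test_groups_ranked_by_rigid_consistency():
    """A group whose bonds can be realized exactly by one rigid placement
    outranks one that can only be realized with residual strain."""
    tight = _abstract_interactions(3)  # EBA primaries coincide with PBRs
    loose = []
    for i in range(3, 6):
        pbr = make_pbr(i, (3.0 * i, 0, 0), (3.0 * i, 1, 0), native_aa="SER")
        # epitope points internally distorted: no rigid motion fits exactly
        offset = (0, 1.5, 0) if i == 4 else (0, 0, 0)
        eba = make_eba(i, np.add((3.0 * i, 0, 0), offset),
                       np.add((3.0 * i, 1, 0), offset))
        loose.append((pbr, eba))
    couples = [Couple(a, b, 0.1) for a, b in
               itertools.combinations(tight, 2)]
    couples += [Couple(a, b, 0.1) for a, b in
                itertools.combinations(loose, 2)]
    groups = expand_groups(couples)
    assert len(groups) == 2
    first = {pbr.site for pbr, _ in groups[0].interactions}
    assert first == {("A", 0), ("A", 1), ("A", 2)}


def test_group_positive_charge_limit():
    inters = _abstract_interactions(4)
    pos = make_pbr(10, (30, 0, 0), (30, 1, 0), aa="LYS", atom_name="HZ1",
                   charged="positive", native_aa="SER")
    pos_inter = (pos, make_eba(10, (30, 0, 0), (30, 1, 0), aa="ASP",
                               atom_name="OD1", backbone=False))
    members = inters[:3] + [pos_inter]
    couples = [Couple(a, b, 0.1)
               for a, b in itertools.combinations(members, 2)]
    groups = expand_groups(couples)
    assert groups and all(g.n_positive <= 1 for g in groups)


def test_design_mutations_recorded():
    inters = []
    for i, (aa, native) in enumerate((("SER", "SER"), ("THR", "SER"),
                                      ("ASN", "ALA"))):
        pbr = make_pbr(i, (float(3 * i), 0, 0), (float(3 * i), 1, 0),
                       aa=aa, rotamer_id=0 if aa != native else "native",
                       native_aa=native)
        inters.append((pbr, make_eba(i, (float(3 * i), 0, 0),
                                     (float(3 * i), 1, 0))))
    couples = [Couple(a, b, 0.0)
               for a, b in itertools.combinations(inters, 2)]
    (group,) = expand_groups(couples)
    assert group.design_mutations == {("A", 1): "THR", ("A", 2): "ASN"}
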