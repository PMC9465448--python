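"""The six-step clash-mutation cascade on constructed scenes.

Each scene plants antigen "blocker" atoms so that specific cascade steps
must fail or succeed; the tests verify both the outcome and, by direct
distance computation, that the earlier steps genuinely had no solution.
"""
import numpy as np
import pytest

from hbdock.fixtures import make_ideal_helix
from hbdock.hbond import salt_bridge_between
from hbdock.mutation import (FORBIDDEN_TARGETS, _surrounding, resolve_clashes,
                             step2_3_salt_bridge, step4_polar, step5_nonpolar)
from hbdock.posing import (ClashRecord, FilterConfig, Pose, RigidTransform,
                           clash_atoms)
from hbdock.rotamers import place_rotamer
from hbdock.structure import Atom, ProteinStructure, Residue

CFG = FilterConfig()
SITE = ("A", 4)


def make_pose(scaffold, antigen_residues, clash_sites=(SITE,)):
    antigen = ProteinStructure(antigen_residues)
    return Pose(None, RigidTransform.identity(), 0.0,
                scaffold_state=scaffold.copy(), antigen_state=antigen,
                clash_records=[ClashRecord(s, antigen_residues[0].site)
                               for s in clash_sites])


def blocker(pos, seq=1, chain="B"):
    return Residue(chain, seq, "ALA", [Atom("CB", "C", np.asarray(pos, float))])


@pytest.fixture()
def ser_helix():
    return make_ideal_helix("AAASAA")


@pytest.fixture()
def met_helix():
    return make_ideal_helix("AAAMAA")


def met_blockers(met_helix, library):
    """One C atom just beyond each MET rotamer's SD: every native rotamer
    clashes, short side chains stay clear."""
    out = []
    for i, rot in enumerate(library["MET"]):
        placed = place_rotamer(met_helix, SITE, rot)
        sd, cb = placed.atom("SD").coord, placed.atom("CB").coord
        u = (sd - cb) / np.linalg.norm(sd - cb)
        out.append(blocker(sd + 0.9 * u, seq=i + 1))
    return out


def test_no_clash_records_is_a_no_op(ser_helix, library):
    pose = make_pose(ser_helix, [blocker((50, 50, 50))], clash_sites=())
    before = {(r.site, a.name): a.coord.copy()
              for r in pose.scaffold_state.residues for a in r.atoms}
    pose = resolve_clashes(pose, library, CFG)
    assert pose.accepted and pose.mutation_records == []
    for r in pose.scaffold_state.residues:
        for a in r.atoms:
            np.testing.assert_array_equal(a.coord, before[(r.site, a.name)])


def test_step1_alternate_native_rotamer(ser_helix, library):
    """A blocker occluding only the native rotamer's OG is resolved by
    repacking, without an amino-acid change."""
    native = place_rotamer(ser_helix, SITE, library["SER"][0])
    og, cb = native.atom("OG").coord, native.atom("CB").coord
    u = (og - cb) / np.linalg.norm(og - cb)
    blk = blocker(og + 0.9 * u)
    # the blocker hard-clashes the native conformation ...
    assert np.linalg.norm(blk.atoms[0].coord - og) < 1.3
    # ... but leaves at least one alternate rotamer clash-free
    free = [rot for rot in library["SER"][1:]
            if not clash_atoms([a for a in
                                place_rotamer(ser_helix, SITE, rot).atoms
                                if a.is_heavy], blk.atoms)]
    assert free
    pose = resolve_clashes(make_pose(ser_helix, [blk]), library, CFG)
    assert pose.accepted
    (rec,) = pose.mutation_records
    assert (rec.from_aa, rec.to_aa, rec.kind, rec.cascade_step) == \
        ("SER", "SER", "clash", 1)


def test_step2_asp_salt_bridge_preferred_over_glu(ser_helix, library):
    """With an antigen LYS reachable by both carboxylates, ASP wins."""
    placed = place_rotamer(ser_helix, SITE, library["ASP"][0])
    od1, cb = placed.atom("OD1").coord, placed.atom("CB").coord
    u = (od1 - cb) / np.linalg.norm(od1 - cb)
    nz = od1 + 3.2 * u
    lys = Residue("C", 1, "LYS", [Atom("NZ", "N", nz),
                                  Atom("CE", "C", nz + 1.5 * u)])
    pose = make_pose(ser_helix, [lys], clash_sites=())
    near_s, near_a = _surrounding(pose.scaffold_state, pose.antigen_state, SITE)
    found = step2_3_salt_bridge(SITE, pose, library, near_s, near_a, set(), CFG)
    assert found is not None
    chosen, partner, step = found
    assert (chosen.aa_type, partner, step) == ("ASP", ("C", 1), 2)
    # GLU could have bridged too, so this is genuinely a priority decision
    assert any(salt_bridge_between(place_rotamer(ser_helix, SITE, r).atoms, lys)
               for r in library["GLU"])


def test_step3_glu_when_asp_cannot_reach(ser_helix, library):
    placed = place_rotamer(ser_helix, SITE, library["GLU"][0])
    oe1, cb = placed.atom("OE1").coord, placed.atom("CB").coord
    u = (oe1 - cb) / np.linalg.norm(oe1 - cb)
    nz = oe1 + 3.2 * u
    lys = Residue("C", 1, "LYS", [Atom("NZ", "N", nz),
                                  Atom("CE", "C", nz + 1.5 * u)])
    # every ASP carboxylate oxygen stays beyond the 4.0 A criterion
    for rot in library["ASP"]:
        p = place_rotamer(ser_helix, SITE, rot)
        assert min(np.linalg.norm(p.atom(o).coord - nz)
                   for o in ("OD1", "OD2")) > 4.0
    pose = make_pose(ser_helix, [lys], clash_sites=())
    near_s, near_a = _surrounding(pose.scaffold_state, pose.antigen_state, SITE)
    found = step2_3_salt_bridge(SITE, pose, library, near_s, near_a, set(), CFG)
    assert found is not None and found[0].aa_type == "GLU" and found[2] == 3


def test_claimed_antigen_charge_not_reused(ser_helix, library):
    placed = place_rotamer(ser_helix, SITE, library["ASP"][0])
    od1, cb = placed.atom("OD1").coord, placed.atom("CB").coord
    u = (od1 - cb) / np.linalg.norm(od1 - cb)
    nz = od1 + 3.2 * u
    lys = Residue("C", 1, "LYS", [Atom("NZ", "N", nz),
                                  Atom("CE", "C", nz + 1.5 * u)])
    pose = make_pose(ser_helix, [lys], clash_sites=())
    near_s, near_a = _surrounding(pose.scaffold_state, pose.antigen_state, SITE)
    assert step2_3_salt_bridge(SITE, pose, library, near_s, near_a,
                               claimed={("C", 1)}, cfg=CFG) is None


class TestStep4Polar:
    def _acceptor_fragment(self, helix, library, backbone=True):
        """A carbonyl O placed for an ideal bond with SER's first rotamer."""
        placed = place_rotamer(helix, SITE, library["SER"][0])
        og, hg1 = placed.atom("OG").coord, placed.atom("HG1").coord
        u = (hg1 - og) / np.linalg.norm(hg1 - og)
        o_pos = hg1 + 1.9 * u
        if backbone:
            atoms = [Atom("N", "N", o_pos + 8 * u + [0, 0, 3.0]),
                     Atom("CA", "C", o_pos + 7 * u + [0, 0, 2.0]),
                     Atom("C", "C", o_pos + 1.23 * u),
                     Atom("O", "O", o_pos)]
            return Residue("C", 1, "ALA", atoms)
        # same geometry, but the acceptor is a side-chain hydroxyl
        atoms = [Atom("N", "N", o_pos + 8 * u + [0, 0, 3.0]),
                 Atom("CA", "C", o_pos + 7 * u + [0, 0, 2.0]),
                 Atom("C", "C", o_pos + 6 * u + [0, 0, 1.0]),
                 Atom("O", "O", o_pos + 6.5 * u + [0, 0, 2.0]),
                 Atom("CB", "C", o_pos + 1.43 * u),
                 Atom("OG", "O", o_pos),
                 Atom("HG1", "H", o_pos + 0.96 * (u + [0.3, 0.3, 0]) /
                      np.linalg.norm(u + [0.3, 0.3, 0]))]
        return Residue("C", 1, "SER", atoms)

    def test_ser_selected_first_in_polar_order(self, ser_helix, library):
        frag = self._acceptor_fragment(ser_helix, library)
        pose = make_pose(ser_helix, [frag], clash_sites=())
        near_s, near_a = _surrounding(pose.scaffold_state,
                                      pose.antigen_state, SITE)
        found = step4_polar(SITE, pose, library, near_s, near_a, CFG)
        assert found is not None and found[0].aa_type == "SER"

    def test_full_cascade_reaches_step4(self, met_helix, library):
        blockers = met_blockers(met_helix, library)
        frag = self._acceptor_fragment(met_helix, library)
        pose = make_pose(met_helix, blockers + [frag])
        pose = resolve_clashes(pose, library, CFG)
        assert pose.accepted
        (rec,) = pose.mutation_records
        assert rec.cascade_step == 4 and rec.to_aa == "SER"

    def test_asn_single_sidechain_bond_rejected(self, ser_helix, library):
        """One hydrogen bond to a *side-chain* atom does not qualify ASN."""
        from hbdock.hbond import is_valid_hbond
        cb = ser_helix[SITE].atom("CB").coord
        # the ASN amide proton that points farthest from CB (so the target
        # sits beyond what a serine/threonine hydroxyl can reach), among
        # rotamers that do not collide with the scaffold itself
        def scaffold_clear(rot):
            p = place_rotamer(ser_helix, SITE, rot)
            return not any(
                clash_atoms([a for a in p.atoms if a.is_heavy],
                            r.heavy_atoms())
                for r in ser_helix.residues if r.site != SITE)

        best = max(
            ((rot, h) for rot in library["ASN"] for h in ("HD21", "HD22")
             if scaffold_clear(rot)),
            key=lambda rh: np.linalg.norm(
                place_rotamer(ser_helix, SITE, rh[0]).atom(rh[1]).coord - cb))
        placed = place_rotamer(ser_helix, SITE, best[0])
        hd = placed.atom(best[1]).coord
        nd2 = placed.atom("ND2").coord
        u = (hd - nd2) / np.linalg.norm(hd - nd2)
        o_pos = hd + 1.9 * u
        acceptor = Atom("O", "O", o_pos)
        for aa in ("SER", "THR"):
            for rot in library[aa]:
                p = place_rotamer(ser_helix, SITE, rot)
                assert not is_valid_hbond(p.atom("HG1"),
                                          p.atom("OG" if aa == "SER" else "OG1"),
                                          acceptor)
        for res_kind in (False, True):
            frag = self._asn_target(o_pos, u, sidechain=not res_kind)
            pose = make_pose(ser_helix, [frag], clash_sites=())
            near_s, near_a = _surrounding(pose.scaffold_state,
                                          pose.antigen_state, SITE)
            found = step4_polar(SITE, pose, library, near_s, near_a, CFG)
            if res_kind:  # backbone partner: the ASN exception applies
                assert found is not None and found[0].aa_type == "ASN"
            else:
                assert found is None or found[0].aa_type != "ASN"

    @staticmethod
    def _asn_target(o_pos, u, sidechain):
        if sidechain:
            return Residue("C", 1, "SER", [
                Atom("N", "N", o_pos + 8 * u + [0, 0, 3.0]),
                Atom("CA", "C", o_pos + 7 * u + [0, 0, 2.0]),
                Atom("C", "C", o_pos + 6 * u + [0, 0, 1.0]),
                Atom("O", "O", o_pos + 6.5 * u + [0, 0, 2.5]),
                Atom("CB", "C", o_pos + 1.43 * u),
                Atom("OG", "O", o_pos),
                Atom("HG1", "H", o_pos + 0.96 * (u + [0.3, 0.3, 0]) /
                     np.linalg.norm(np.asarray(u) + [0.3, 0.3, 0]))])
        return Residue("C", 1, "ALA", [
            Atom("N", "N", o_pos + 8 * u + [0, 0, 3.0]),
            Atom("CA", "C", o_pos + 7 * u + [0, 0, 2.0]),
            Atom("C", "C", o_pos + 1.23 * u),
            Atom("O", "O", o_pos)])


def test_step5_nonpolar_contact(met_helix, library):
    """Carbon-only blockers offer no polar partners; the cascade falls
    through to a nonpolar mutation in contact with the antigen."""
    blockers = met_blockers(met_helix, library)
    pose = resolve_clashes(make_pose(met_helix, blockers), library, CFG)
    assert pose.accepted
    (rec,) = pose.mutation_records
    assert rec.cascade_step == 5
    assert rec.to_aa in ("ALA", "VAL", "LEU", "ILE", "PHE")
    # ALA was skipped only because its CB cannot reach a contact
    cb = place_rotamer(met_helix, SITE, library["ALA"][0]).atom("CB").coord
    nearest = min(np.linalg.norm(b.atoms[0].coord - cb) for b in blockers)
    if rec.to_aa != "ALA":
        assert nearest >= 4.5


def test_step5_requires_contact(ser_helix, library):
    """Clash-free rotamers without any C/S neighbour are not selected."""
    polar_only = Residue("C", 1, "ALA", [Atom("N", "N", (30.0, 0, 0)),
                                         Atom("O", "O", (31.0, 0, 0)),
                                         Atom("CA", "C", (60.0, 0, 0)),
                                         Atom("C", "C", (61.0, 0, 0))])
    pose = make_pose(ser_helix, [polar_only], clash_sites=())
    near_s = [r for r in pose.scaffold_state.residues if r.site != SITE]
    near_a = [pose.antigen_state.residues[0]]
    # strip the C atoms out of reach: only N/O remain near the site
    assert step5_nonpolar(SITE, pose, library, near_s,
                          [Residue("C", 1, "ALA", polar_only.atoms[:2])],
                          CFG) is None


def test_step6_irreconcilable_clash_rejects_pose(ser_helix, library):
    """A blocker riding on the CB position defeats every amino acid."""
    res = ser_helix[SITE]
    ca, cb = res.atom("CA").coord, res.atom("CB").coord
    u = (cb - ca) / np.linalg.norm(cb - ca)
    pose = resolve_clashes(make_pose(ser_helix, [blocker(cb + 1.0 * u)]),
                           library, CFG)
    assert pose.status == "rejected"
    assert "irreconcilable" in pose.reject_reason


def test_forbidden_amino_acids_never_introduced(met_helix, ser_helix, library):
    scenes = []
    scenes.append(resolve_clashes(
        make_pose(met_helix, met_blockers(met_helix, library)), library, CFG))
    native = place_rotamer(ser_helix, SITE, library["SER"][0])
    og, cb = native.atom("OG").coord, native.atom("CB").coord
    u = (og - cb) / np.linalg.norm(og - cb)
    scenes.append(resolve_clashes(
        make_pose(ser_helix, [blocker(og + 0.9 * u)]), library, CFG))
    for pose in scenes:
        for rec in pose.mutation_records:
            assert rec.to_aa not in FORBIDDEN_TARGETS
            assert rec.to_aa not in ("ARG", "LYS")
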