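"""Watch the clash-mutation cascade rescue a clashing side chain.

A methionine on the scaffold clashes with planted antigen atoms in every
rotamer. The cascade tries repacking (step 1), salt bridges (2-3), polar
mutations (4) and finally nonpolar mutations (5); here the carbon-only
antigen offers no polar partners, so a nonpolar mutation in van der Waals
contact wins.
"""
import warnings

import numpy as np

from hbdock import FilterConfig, load_library, make_ideal_helix, resolve_clashes
from hbdock.posing import ClashRecord, Pose, RigidTransform
from hbdock.rotamers import place_rotamer
from hbdock.structure import Atom, ProteinStructure, Residue

warnings.simplefilter("ignore")

library = load_library()
helix = make_ideal_helix("AAAMAA")
site = ("A", 4)

# one carbon blocker just beyond each MET rotamer's SD atom
blockers = []
for i, rot in enumerate(library["MET"]):
    placed = place_rotamer(helix, site, rot)
    sd, cb = placed.atom("SD").coord, placed.atom("CB").coord
    u = (sd - cb) / np.linalg.norm(sd - cb)
    blockers.append(Residue("B", i + 1, "ALA", [Atom("CB", "C", sd + 0.9 * u)]))

pose = Pose(None, RigidTransform.identity(), 0.0,
            scaffold_state=helix.copy(),
            antigen_state=ProteinStructure(blockers),
            clash_records=[ClashRecord(site, ("B", 1))])
pose = resolve_clashes(pose, library, FilterConfig())

print("pose status:", pose.status)
for rec in pose.mutation_records:
    print(f"  {rec.site[0]}:{rec.site[1]}  {rec.from_aa} -> {rec.to_aa}"
          f"  (cascade step {rec.cascade_step}: {rec.evidence})")
# Step 5 fired: no alternate MET rotamer fits (step 1), the antigen has no
# ARG/LYS for a salt bridge (2-3) and no polar atoms to bond (4), but a
# nonpolar side chain can pack against the antigen carbons within 4.5 A.
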