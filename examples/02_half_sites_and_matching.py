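"""Inspect hydrogen-bond half-sites and the pairwise compatibility test.

Builds a serine on an ideal helix, lists its half-sites (donor HG1,
acceptor OG, backbone O/HN), and shows the distance-and-angles agreement
check between a scaffold pair and an epitope pair.
"""
import warnings

import numpy as np

from hbdock import (couple_compatible, make_ideal_helix, make_pbrs,
                    pair_geometry)

warnings.simplefilter("ignore")

helix = make_ideal_helix("AASAA")
ser = helix[("A", 3)]
print(f"half-sites of {ser.aa_type} A:3")
for pbr in make_pbrs(ser):
    d_primary = np.linalg.norm(pbr.primary - pbr.pbr_atom.coord)
    print(f"  {pbr.atom_name:>4} {pbr.polarity:<8} backbone={pbr.is_backbone_atom}"
          f"  |atom->primary| = {d_primary:.2f} A")

# pair geometry of the serine donor with a backbone carbonyl two turns away
pbrs = {(p.site, p.atom_name): p
        for r in helix.residues for p in make_pbrs(r)}
g = pair_geometry(pbrs[(("A", 3), "HG1")], pbrs[(("A", 5), "O")])
print(f"\nscaffold pair: D = {g.D:.2f} A, angles = "
      f"{g.ang_1p:.0f}/{g.ang_2p:.0f}/{g.ang_1s:.0f}/{g.ang_2s:.0f} deg")
print("compatible with itself:", couple_compatible(g, g))
# An epitope pair must match D within 1.8 A and each angle within 70 deg
# for the two bonds to be realizable by one rigid placement.
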