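# Methods

`hbdock` implements a simultaneous dock-and-mutate strategy for
fixed-backbone binding scaffolds (affibody/DARPin-style binders whose
paratope is a set of mutable surface residues on a rigid fold). Instead of
sampling rigid-body orientations and scoring them, the method enumerates
hydrogen bonds that *could* exist between the two proteins — considering
both the native paratope side chains and candidate polar mutations — and
only ever constructs poses that realize at least three of them. This note
records the model, the constants, the numerical choices, and what the
synthetic test systems do and do not demonstrate.

## Half-site construction

Every polar group capable of hydrogen bonding is reduced to a *half-site*.

On the scaffold side (PBR, paratope binding region) a half-site is a polar
atom — a donatable hydrogen or an acceptor O/N — plus two constructed
points on the ray from its antecedent atom through the polar atom: the
**primary point** 1.25 Å beyond the atom (the ideal location of the partner
atom) and the **secondary point** 1 Å further out (an orientation marker
that penalizes acute approach geometries). On the epitope side (EBA,
epitope binding atom) the primary point is the polar atom itself and the
secondary point is its antecedent's position.

The registry of polar atoms covers the backbone carbonyl O (antecedent C)
and amide HN (antecedent N) of every residue, the terminal OT1/OT2 and
HN1–HN3 groups at chain ends only, and the side-chain donors/acceptors of
ARG, LYS, ASP, GLU, SER, THR, TYR, ASN, GLN, HIS and TRP. Hydroxyl and
imidazole acceptors use midpoint antecedents (e.g. serine OG's antecedent
is the HG1/CB midpoint) so that the construction ray bisects the lone-pair
region. Histidine is modelled as the ND1-protonated tautomer: HD1 donates,
NE2 accepts (antecedent = CD2/CE1 midpoint). Epitope residues must be
solvent exposed to contribute half-sites; exposure means a per-residue
Shrake–Rupley solvent-accessible area above 0.1 Å² (probe 1.4 Å, 960
sphere points per heavy atom; the 0.1 Å² margin absorbs point-mesh noise
that a strict "> 0" rule would amplify).

Missing polar hydrogens are built at ideal covalent geometry (N–H 1.0 Å,
O–H 0.96 Å; sp2 protons in-plane, sp3 protons staggered). Rotatable
hydroxyl protons default to the anti conformation about the C–O bond so
that placement is deterministic.

## Type screen

A donor must meet an acceptor, and the amino-acid classes must form one of
the allowed combinations: scaffold backbone with anything; any scaffold
side chain except ARG/LYS/GLN with antigen backbone; ARG/LYS side chains
only with ASP/GLU (and vice versa); and the low-entropy polar set
{HIS, ASN, ASP, TYR, SER, THR, TRP} with itself, except the ASN–ASP
combination (both carry multiple polar groups and tend to form bifurcated,
poorly specific contacts). At most one positively charged scaffold residue
may appear per couple and per solution.

## Pairwise matching

For two half-sites of one protein, one distance and four angles are
computed on the quadrilateral S1–P1–P2–S2 (P primary, S secondary): the
distance |P1P2| and the interior angles at the four vertices. A scaffold
pair and an epitope pair are *compatible* when the distances agree within
`d_limit` = 1.8 Å and the four corresponding angles agree within `a_limit`
= 70°, under a positional assignment of scaffold half-site *i* to epitope
half-site *i*; both assignments of a candidate couple are tested. The
default limits admit 85% of the hydrogen bonds observed in natural
antibody–antigen interfaces, which is the calibration that motivated these
constants. Pairs within one residue are skipped (they cannot enlarge the
interface). Couple enumeration is exact: every pair-of-pairs within the
distance window is tested, vectorized over precomputed pair-geometry
tables; on large problems only the best `max_couples` (200 000) couples by
self-consistency are materialized.

Each couple carries a **consistency score**: its worst normalized deviation
(distance deviation over `d_limit`, angle deviations over `a_limit`).
A score of 0 means the two bonds are exactly co-realizable by one rigid
placement.

## Group expansion

Interactions (PBR–EBA bonds) form a compatibility graph whose edges are
the couples. A *solution group* is a clique of at least three
interactions; each group defines one candidate pose. Two families of
cliques are generated and merged:

- **maximal cliques** of the graph (bounded enumeration), and
- **growth chains**: each of the best-scoring triangles is extended one
  interaction at a time, always choosing the candidate whose epitope
  primary atom has the smallest residual under the least-squares rigid
  superposition of the current group, and every intermediate size is
  emitted. Because the three-point superposition is the least determined,
  the first addition is branched over the top few candidates.

The growth chains exist because the pairwise tolerances are deliberately
permissive: a maximal clique usually mixes one rigidly realizable bond set
with geometrically looser bystanders that doom the pose at validation.
Emitting the nested subgroups preserves the clean cores as candidates in
their own right. Groups that realize the same physical bonds through
different rotamers are collapsed (the variant with fewest mutations wins),
groups are ranked by their own superposition RMSD (the direct measure of
co-realizability; ties go to the larger group), and at most `max_poses`
(2000) candidates proceed to pose construction. Ranking candidates by
size alone was tried first and rejected: under 70° tolerances the largest
cliques are essentially never realizable, and the candidate budget is
spent before any valid pose is reached.

## Design mutations

At every mutable paratope site, side-chain half-sites are also generated
for up to five structurally diverse rotamers of each amino acid in the
polar design alphabet (ARG, LYS, ASP, GLU, HIS, ASN, TYR, SER, THR, TRP;
GLN is omitted because its side chain participates in no allowed scaffold
pairing class). Diversity is greedy farthest-point selection on side-chain
heavy-atom RMSD after placement at the site, seeded with the most probable
rotamer. A group whose bonds use a non-native rotamer implies the
corresponding *design mutations*. Rotamers come from a bundled
backbone-independent chi-mode table (the canonical gauche/trans
combinations with generic frequencies); a user-supplied table in the same
plain-text format (`AA chi1 chi2 chi3 chi4 weight`) is accepted, so a
licensed rotamer library can be dropped in without code changes. Side
chains are built by superposing an ideal-geometry residue template onto
the site's N/CA/C frame, rebuilding CB, and driving each chi dihedral to
its target; backbone atoms are never moved.

## Pose construction and filters

For each group, the antigen is rigidly placed by Kabsch superposition of
its EBA primary atoms onto the group's PBR primary points (equal weights,
proper rotation). Design rotamers are installed; a pose is rejected
outright if a newly placed rotamer clashes with another placed rotamer or
with any residue outside the mutable set.

Steric clash between two residues (heavy atoms only) means: any pair
closer than 1.3 Å, more than one pair closer than 1.8 Å, or exactly one
sub-1.8 Å pair involving a backbone atom. These deliberately loose bounds
assume a downstream force-field minimization can relax small overlaps.

A coarse-grained filter then screens interface size and gross overlap.
Each residue contributes a backbone and a side-chain bounding sphere
(center = heavy-atom centroid, radius = distance to the farthest atom).
A pose is rejected as clashing when any scaffold–antigen sphere pair
overlaps by more than 3.39 Å (with a config switch to read the constant as
a minimum center–center distance instead), and as too small when fewer
than 12 sphere pairs are in contact. Contact means a surface gap of at
most 4.0 Å: the spheres bound atom *centers*, so two units whose spheres
are separated by up to roughly two carbon van der Waals radii can still be
in atomic contact. (A 1 Å pad was tried first and rejects even a perfectly
docked complex of small residues, which have near-zero sphere radii.)

All-atom validation follows: every designed bond is re-measured on
realized coordinates and must satisfy the hydrogen-bond criterion —
acceptor–hydrogen distance < 2.5 Å and acceptor–hydrogen–donor angle
> 120°; one failure rejects the pose. Remaining scaffold–antigen clashes
reject the pose when they involve a non-mutable residue, a designed-bond
residue, or the backbone of a mutable residue; clashes confined to side
chains of other mutable residues are recorded for the mutation stage.

## Clash-mutation cascade

Recorded clash sites are processed in ascending residue order (earlier
fixes are visible to later checks). For each site the first succeeding
step wins:

1. an alternate rotamer of the current amino acid with no clash against
   any residue within 10 Å;
2. an ASP rotamer forming a salt bridge (carboxylate O within 4.0 Å of a
   charged N — the classic distance criterion) with an antigen ARG/LYS not
   already claimed in this pose;
3. a GLU rotamer doing the same (ASP is preferred: smaller side chain,
   lower entropic cost);
4. a polar rotamer making new hydrogen bonds, searched as SER, THR, ASN,
   ASP, HIS with minimum bond counts 1, 1, 2, 2, 2; an ASN with a single
   bond to an antigen *backbone* atom is also accepted; GLN and GLU are
   excluded as high-entropy side chains;
5. a nonpolar rotamer (ALA, VAL, LEU, ILE, PHE) with at least one C/S atom
   within 4.5 Å of an antigen C/S atom; MET, TRP, TYR are excluded;
6. otherwise the pose is rejected as an irreconcilable clash.

ARG and LYS are never introduced by the cascade. Library order breaks
ties among qualifying rotamers. The 10 Å "surrounding" radius is a safe
superset: the clash conditions themselves act below 1.8 Å.

## Synthetic test systems

The fixture generator builds an ideal α-helix (φ = −57°, ψ = −47°, ideal
bond lengths/angles) with donor residues (serine by default) on one face,
and plants one short antigen peptide per requested bond: an ALA
pentapeptide placed so its middle backbone carbonyl O sits exactly at the
donor's primary point with the C=O bond on the donor axis — an ideal,
linear hydrogen bond. The remaining roll angle is chosen to hug the
scaffold surface without touching it, which gives the complex a realistic
interface size; the assembled antigen is then moved by a seeded rigid
motion so that recovering the planted pose genuinely exercises matching
and superposition. Generation is a pure function of the fixture spec.

What these fixtures show: that the pipeline recovers exactly co-realizable
bond sets, rejects under-sized groups, applies every filter at its stated
constant, and drives the mutation cascade in order. What they do not
show: performance on real protein shapes (loops, packed side chains,
partial burial), discrimination among competing epitopes, or the quality
ranking of poses — the method deliberately leaves pose ranking and
refinement to downstream tools. Planted fixtures use small problem sizes
(3–6 bonds, candidate budget 200 poses in tests) chosen to keep the whole
suite fast; the defaults (2000 poses) are the method's operating point.

## Determinism and degeneracies

The core pipeline contains no randomness; identical inputs and
configuration give byte-identical summaries. All candidate orderings are
total (score, then size, then lexicographic keys). Collinear three-point
systems superpose correctly (SVD-based Kabsch with the proper-rotation
branch); exactly coincident primary points are an error. Couples at
exactly the distance or angle limit are excluded (strict inequalities,
matching the printed thresholds). Alternate PDB locations collapse to the
highest-occupancy conformer; waters and hetero compounds are dropped on
input.

## Known limitations

- Hydrophobic-contact matching is not part of pose identification; only
  hydrogen bonds seed poses.
- Backbone-independent rotamers only; no off-rotamer minimization.
- The bounded clique search (`max_couples`, `max_ranked_couples`,
  `max_grown_triangles`, `growth_branches`) is exact on small problems but
  heuristic at scale: a realizable group outside the candidate budget can
  be missed.
- No energetic scoring: accepted poses are unranked beyond geometric
  self-consistency, and refinement is left to the user.
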