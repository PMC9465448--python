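# hbdock

Simultaneous dock-and-mutate design of fixed-backbone binding scaffolds.

Small non-antibody binders — affibodies, DARPins and their relatives —
recognize their targets through mutations at a fixed set of surface
positions on a rigid fold. Conventional rigid-body docking handles such
scaffolds poorly: it docks a *constant* sequence, so any pose that would
only work after mutating a surface residue is thrown away before design
ever starts. `hbdock` inverts the procedure. It enumerates the hydrogen
bonds that could form between the scaffold paratope — with both its native
side chains and candidate polar mutations, rotamer by rotamer — and the
solvent-exposed epitope, finds sets of three or more bonds that a single
rigid placement can realize simultaneously, builds exactly those poses,
and then rescues any clashing mutable side chain with an ordered,
feature-based mutation cascade.

## Method in brief

Every polar group becomes a *half-site*: the scaffold side (PBR) is a
donatable H or acceptor atom plus an ideal partner position 1.25 Å along
the bond axis and an orientation marker 1 Å further; the epitope side
(EBA) is the exposed polar atom plus its antecedent. For two half-sites of
one protein, the distance between primary points and the four angles of
the quadrilateral S1–P1–P2–S2 summarize their relative geometry. A
scaffold pair and an epitope pair are compatible — realizable as two
hydrogen bonds by one rigid motion — when

|D₁ − D₂| < d_limit, |∠PBRᵢ − ∠EBAᵢ| < a_limit (four angle pairs),

with d_limit = 1.8 Å and a_limit = 70°. Compatible couples are expanded
into solution groups (cliques of mutually compatible interactions); each
group is realized by Kabsch superposition of the epitope atoms onto the
ideal partner positions, screened by a coarse-grained sphere filter
(minimum 12 sphere contacts, 3.39 Å separation budget) and steric-clash
rules (1.3 Å / 1.8 Å heavy-atom conditions), and validated atom-by-atom:
every designed bond must satisfy d(A···H) < 2.5 Å and ∠A–H–D > 120°.
Surviving clashes of mutable residues enter a six-step cascade — repack,
ASP salt bridge, GLU salt bridge, polar mutation (SER/THR/ASN/ASP/HIS),
nonpolar mutation (ALA/VAL/LEU/ILE/PHE), reject. See `docs/methods.md`
for the full model, constants and design choices.

## Worked example

`examples/01_dock_planted_complex.py` builds a synthetic complex with
three ideal serine→carbonyl bonds planted between a helical scaffold and
three antigen peptides, displaces the antigen by a random rigid motion,
and docks it back:

```
scaffold: 12 residues; antigen: 15 residues in 3 fragments
half-sites: 326 scaffold (native + mutated rotamers), 36 epitope
couples: 200000; candidate groups: 200; accepted poses: 9
planted pose recovered: 3 designed H-bonds, superposition RMSD 0.0000 A
  SER A:3/HG1  ->  ALA B:3/O
  SER A:7/HG1  ->  ALA C:3/O
  SER A:10/HG1  ->  ALA D:3/O
```

The recovered pose realizes exactly the three planted bonds with zero
superposition residual; the other accepted poses are alternative bond sets
the permissive tolerances legitimately admit. The other examples show
half-site construction/pairwise matching (`02`) and the clash-mutation
cascade rescuing a blocked methionine (`03`).

## Command line

```bash
hbdock make-fixture --bonds 3 --seed 1 --out fixture/
hbdock dock --scaffold fixture/scaffold.pdb --antigen fixture/antigen.pdb \
    --paratope A:1-12 --variable A:3,A:7,A:10 --epitope B:1-5,C:1-5,D:1-5 \
    --out run/
hbdock validate-pose run/pose_0000.pdb --scaffold-chains A
```

`dock` writes one PDB per accepted pose (with a REMARK block listing the
designed bonds and mutations), a TSV of mutation records, and a JSON run
summary; all thresholds can be overridden on the command line or in a
YAML config.

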