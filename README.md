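# cgline

A toolkit for the **CGsmiles line notation**: strings that encode a molecule
at several resolutions at once — coarse-grained (CG) beads, residues, blocks,
all the way down to atoms — together with the *mapping* that connects each
level to the next.

## Why

Coarse-grained force fields such as Martini 3 group atoms into effective
interaction sites ("beads").  Reproducing or sharing such a model requires
the mapping: which atoms form each bead, with which weights the bead position
is computed, and how beads bond.  Conventional workflows scatter this over
mapping files, topology files and order-sensitive coordinate files.  The
notation puts everything into one string:

```
{[#OH][#PEO]|4[#OH]}.{#OH=[$]O,#PEO=[$]COC[$]}
```

The first brace block is the coarsest graph (here: a PEG chain written with
the `|4` multiplication shorthand); each following block defines, per node
label, the *fragment* that replaces the node one resolution finer.  Bracketed
bonding descriptors adapted from BigSMILES — undirected `[$]`, directed
`[>]`/`[<]`, and the squash connector `[!]` that merges atoms shared between
beads — say how neighboring fragments connect.  Coarse bond orders 0–4 cover
virtual particles (order 0: no finer-level counterpart) and linearized rings
(order ≥ 2: one CG bond standing for several atomistic bonds).  Node
annotations carry charges (`q`), mapping weights (`w`), chirality (`x=R/S`)
and wildcard selections (`s=`).

The package provides, as a library-first API with a thin `cgline` CLI on top:

* **parsing** of the coarse-graph dialect and of OpenSMILES-based atomic
  fragments (hand-written parser; hydrogen assignment is deferred until the
  molecule is fully assembled),
* **resolution** (`MoleculeResolver`): instantiate fragments, match bonding
  descriptors along coarse-edge order, merge squash atoms, prune virtual
  particles, normalize aromaticity by delocalization-induced molecular
  equivalence (DIME), complete hydrogens, and report per level both graphs
  plus the fine→coarse membership map with weights,
* **writing** strings back (isomorphic round trip) and exporting plain
  OpenSMILES, including best-effort CIP translation of `x=R/S` annotations
  into `@`/`@@`,
* **sampling** (`MoleculeSampler`): grow concrete molecules from
  fragment-only strings describing statistical copolymers, with tunable
  composition and seeded determinism,
* **fingerprinting**: the 2 × 120 Martini solute–solvent interaction
  fingerprint (20 pairwise levels × 6 bead-size combinations, counted against
  water and an organic solvent) plus a conformer-free molecular-volume
  feature, and a census of the special syntax features a CG library uses.

## Worked example

```python
import cgline as cg

# 2-pentene split into two beads; "=" before a descriptor sets the bond order
resolved = cg.resolve("{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}")
print(cg.molecular_formula(resolved.molecule))   # C5H10
print(cg.export_smiles(resolved.molecule))       # CC=CCC

# the crown ether 18-crown-6: a cyclic hexamer of PEO
crown = cg.resolve("{[#PEO]1[#PEO]|4[#PEO]1}.{#PEO=[$]COC[$]}")
print(cg.molecular_formula(crown.molecule))      # C12H24O6
```

Running `python examples/resolve_multiresolution.py` on a three-level
polymer prints:

```
level 1: 2 nodes ['blockA', 'blockB'] -> 4 finer nodes
level 2: 4 nodes ['PEO', 'PEO', 'PMA', 'PMA'] -> 40 finer nodes
molecular formula: C12H22O6
```

i.e. two generic blocks refine to four residues, which refine to the full
40-atom molecule; the membership map then tells which atoms (with which
weights) form each residue.  The other example scripts cover statistical
copolymer sampling (`polymer_sampling.py`), the interaction fingerprint
(`martini_fingerprint.py`) and the syntax census (`syntax_census.py`).

A note on order: descriptor matching scans fragments in written order along
the coarse edges as written, so a handful of strings resolve to different
isomers when their coarse nodes are permuted.  `cgline validate
--check-edge-order` detects such strings; fully labelled descriptors make a
string permutation-proof (see `tests/test_resolver.py`).

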