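# Methods

This note documents the semantics the package implements, the choices made
where the notation leaves room, and what the synthetic test inputs do and do
not establish.

## The notation model

A string is a sequence of brace-enclosed resolution blocks joined by
periods.  Block 1 is the *base graph* — the coarsest representation — in a
SMILES-derived dialect for arbitrary graphs: nodes `[#label;annotations]`,
linear chaining, parenthesised branches, ring-closure markers, bond-order
symbols `. - = # $` (orders 0–4) and a read-side multiplication operator
`|n`.  Every later block is a fragment dictionary `#NAME=body` assigning to
each coarser node label a finer-resolution subgraph, written either in the
same coarse dialect or (typically for the last block) in OpenSMILES plus
extensions.  The dialect of the last block is declared by the caller
(`last_dialect`, default `open_smiles`); all earlier fragment blocks are
coarse-dialect by construction.

Bond orders at a coarse level are *projection counts*, not chemistry: an
order-n edge means n descriptor pairs are consumed between the two fragment
copies (rings mapped onto linear CG graphs raise the order by one per extra
bond), and order 0 marks a virtual edge.  A particle whose edges are all
virtual has no finer-resolution image and is dropped before fragment lookup.
The chemical order of each created bond comes from the descriptors
themselves: a bond symbol written between host and descriptor must be
declared by both partners.

### Ring markers

Markers may be reused after closure, `%` consumes *all* following digits
(unlike OpenSMILES), and a marker only closes against a non-consecutive
node.  A closing attempt against an adjacent node instead opens the marker
in parallel; this makes `[#A]1[#B]1[#C]1[#D]1` yield the two closure edges
A–C and B–D on top of the three chain edges, and makes a genuinely duplicate
edge (same unordered pair twice) a parse error — multiplicity is expressed
through bond orders, never parallel edges.

### Annotations

Key–value pairs separated by `;` inside the node bracket.  Implicit keys:
`q` charge (elementary charges, signed decimals), `w` mapping weight
(non-negative decimals, default 1), `x` chirality (R/S), `s` selection list.
Positional convention: `(q, w)` on coarse nodes, `(w, x)` on atoms — a
positional value fills the next unassigned slot, so `[C;1;S]` equals
`[C;w=1;x=S]`.  Values may not contain `=` or `;`; no escaping is defined,
so such values are rejected.

## Atomic dialect and hydrogens

The OpenSMILES subset parser (hand-written; organic subset, bracket atoms
with isotope/explicit-H/charge, branches, rings, `:` aromatic and `/ \`
stereo bonds) defers hydrogen assignment until the whole molecule is
assembled, because unconsumed bonding descriptors become hydrogens.  As a
consequence — and deliberately unlike strict OpenSMILES — a bracket atom
without an explicit hydrogen count is valence-filled exactly like a bare
organic-subset atom (`[C;x=S]` in a printed alanine fragment receives its
H); write `[CH0]` to suppress.  Charged atoms without an explicit count are
never filled.  Completion uses the smallest standard valence that
accommodates the bond-order sum (N 3/5, P 3/5, S 2/4/6); over-valent atoms
receive none and log a warning.  Each unconsumed descriptor adds one
hydrogen first, where the element has room.

## Aromaticity (DIME)

Aromatic flags are taken verbatim from the fragments and normalized once on
the assembled molecule: per connected aromatic system, atoms that could
accept one more bond without charging are matched pairwise (perfect matching
on the aromatic subgraph).  Two or more distinct matchings — delocalization-
induced molecular equivalence — keep the flags; exactly one demotes the
system to explicit single/double bonds (thiophene, furan, pyrrole); none
triggers a correction in which unmatched atoms absorb the slack as implicit
hydrogens, and an error if an explicit H count forbids that.  Kekulé orders
are always assigned (needed for hydrogen counts); matchings are enumerated
with early exit at two, so cost is negligible for molecular ring systems.
Charged delocalized systems (e.g. cyclopentadienyl) are outside this model
and will be demoted.

## Resolution and matching order

One fragment copy per non-virtual coarse node; coarse edges are processed in
order of first appearance in the string, and within a pair of copies the
scan is (fragment-node written order) × (per-node descriptor written order),
first compatible unconsumed pair wins.  Compatibility: equal labels and
declared bond orders; `$`↔`$`, `>`↔`<`, `!`↔`!`.  A matched `!` pair merges
the two host atoms: element and aromaticity must agree, annotations are
unioned (conflicts error), weights take the maximum, edges are unioned, and
the merged atom belongs to both parent beads.  Hydrogens inherit the full
membership of their heavy atom, so a hydrogen on a shared atom also belongs
to both beads; membership bookkeeping therefore balances as
Σ|membership(heavy)| = n_heavy + n_merges.

First-match resolution is order-sensitive by design: permuting coarse edges
can change the isomer when equivalent descriptors compete (the ethylpyridine
constructions in the tests flip between the 4- and 2-isomer).  Distinctly
labelled descriptors make a string permutation-proof; the CLI's
`validate --check-edge-order` re-resolves under permuted edge order and
reports affected entries.

## Wildcards and selections

`[*;s=a,b,0]` enumerates variants over the Cartesian product of all
selection lists (`enumerate_variants` / `variant(i)`; plain `resolve`
refuses).  Token `0` removes the atom and contracts its bonds (two
neighbors are joined by a bond of the larger order; more than two is an
error) — the POPC-style tail `[*;s=C,0][*;s=C,0]` gives 4 raw variants and 3
distinct tail lengths.  At a coarse level the tokens name fragment labels,
with the same `0` semantics; a fragment-level choice applies to every copy
of that fragment.

## Chirality and cis/trans

Chirality is stored as the explicit R/S annotation, never as order-dependent
`@`/`@@` — fragment assembly would scramble neighbor order.  Validation
requires three distinct neighbors after hydrogen completion, with all
hydrogens collapsed to one (the printed alanine fragment passes; `CC` with a
chiral mark does not).  On SMILES export the annotation is translated via a
best-effort CIP ranking (BFS spheres of atomic number with phantom atoms for
multiple bonds, depth 8, no further tie-breaks); ties drop the mark with a
warning.  The translation is verified against rdkit's CIP labeller in the
tests.  Cis/trans marks follow OpenSMILES `/ \` semantics, are carried
through assembly as written (one mark pair suffices even when substituents
sit in different fragments), and are validated to flank a double bond.

## Writer

Output is deterministic and isomorphic to the input — byte identity is not a
contract (node order is preserved, ring markers are renumbered from the
smallest free integer, `|n` is never emitted, default annotations q=0/w=1
are dropped on coarse nodes) — but printed fragment bodies of the simple
forms round-trip byte-identically, including prefix descriptors
(`[$]CC[$][$]`) and explicitly written atom weights (`[O;w=1]`).  No
canonicalization (Morgan-style) is attempted.

## Sampler

Fragment-only strings are grown by: draw the first unit from the composition
distribution; repeatedly pick an open descriptor uniformly at random, draw a
partner type from the composition restricted and renormalized to types
offering a compatible descriptor, connect through the partner's first
compatible descriptor in written order; stop exactly at the node-count
target or at the first crossing of the molar-mass target (interior-unit
masses: written atoms plus completion hydrogens with all descriptors
consumed).  The notation itself carries no reaction probabilities; this
process is the package's documented choice, seeded and deterministic.
Per-step type probability is therefore composition × availability, which
recovers requested fractions within sampling error (checked at 500 samples
of length 50).  Deadlocks (e.g. all-`>` fragments) are reported with a
census of the remaining descriptors.

## Fingerprint and census

20 pairwise interaction levels × 6 unordered size combinations (order:
regular–regular, regular–small, regular–tiny, small–small, small–tiny,
tiny–tiny) give the 120 interaction types, indexed level-major.  The
fingerprint holds two 120-blocks — solute beads × water beads and solute
beads × organic-solvent beads — plus the solute volume.  The level matrix is
force-field input (symmetric TSV; ionic bead types are simply absent from
it); bead sizes follow the Martini type-name convention (`T…` tiny, `S…`
small, else regular), and trailing capital letters that disambiguate
fragments sharing a type are stripped.  The volume feature is pluggable; the
default is the conformer-free bond/ring-corrected additive van-der-Waals
scheme of Zhao, Abraham & Zissimos (2003) (checked: methane 25.86 Å³,
benzene 81.2 Å³).  The census flags eleven syntax features per entry
(squash, virtual edges, linearized rings, charges, weights, chirality,
cis/trans, split aromaticity, selections, directed descriptors, descriptor
bond orders).

## Synthetic inputs and their limits

Property tests run on generator output: random coarse trees (degree ≤ 4, up
to 8 nodes, optional ring, optional order-2 edge, optional squash/directed/
virtual features) with fragment dictionaries constructed to be resolvable —
per-edge unique descriptor labels when labels are unique, generic `[$]`
otherwise; small C/N/O bodies with capacity-aware descriptor placement.  A
separate token-level composer emits random valid non-aromatic SMILES
(chains, branches, double/triple bonds, one ring) for oracle comparisons
against rdkit.  These inputs exercise the grammar and the matching machinery
broadly, but they are not real force-field mappings: they contain no
multi-ring fused systems at the CG level, no charged atoms, and bead labels
are synthetic.  Passing them demonstrates grammar/resolution/round-trip
correctness, not coverage of every published Martini entry; the library-wide
check is wired to run whenever the published 407-entry collection is placed
at `data/martini3_library.tsv`.

## Known limitations

* CG graphs whose bonded topology deviates from the mapped connectivity
  (e.g. sterols parametrized for numerical stability) cannot be resolved
  from the bonded graph; strings must follow the mapped connectivity.
* Virtual particles are not GROMACS virtual sites; a virtual site describing
  real particles is an ordinary node.
* Molar-mass targeting in the sampler assumes atomic-dialect fragments.
* `@`/`@@` in input fragments is parsed but ignored (annotate `x=` instead);
  CIP export is best-effort.
* Block copolymers of statistical blocks and probability-annotated
  descriptors are out of scope.
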