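"""Parse a multi-resolution string and walk it down to atoms.

A PEG-like polymer is written at three resolutions: blocks, residues and
atoms.  Resolving yields, per level, the coarser graph and its finer image
plus the membership map connecting them.
"""

import cgline as cg

STRING = ("{[#blockA][#blockB]}."
          "{#blockA=[#PEO][#PEO][$],#blockB=[$][#PMA][#PMA]}."
          "{#PEO=[$]COC[$],#PMA=[$]CC[$]C(=O)OC}")

resolved = cg.MoleculeResolver(STRING).resolve()

print("input:", STRING)
for level, (coarse, fine) in enumerate(resolved.graphs(), start=1):
    labels = [coarse.nodes[n].get("label", coarse.nodes[n].get("element"))
              for n in coarse.nodes]
    print(f"level {level}: {coarse.number_of_nodes()} nodes {labels} "
          f"-> {fine.number_of_nodes()} finer nodes")

molecule = resolved.molecule
print("molecular formula:", cg.molecular_formula(molecule))
print("SMILES:", cg.export_smiles(molecule))

# membership: which atoms belong to the first PEO residue (weights included)
last = resolved.layers[-1]
peo_atoms = [n for n, beads in last.membership.items() if 0 in beads]
print(f"atoms mapped to residue 0 (first PEO): {len(peo_atoms)}")
# Each atom carries a weight inside its bead (default 1); bead positions in
# simulations are weight-averaged over exactly these atoms.
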