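"""Compute a Martini solute-solvent interaction fingerprint.

The fingerprint counts, for every of the 120 symmetric interaction types
(20 levels x 6 bead-size combinations), how many (solute bead, solvent bead)
pairs realize it -- once against water, once against an organic solvent --
and appends the solute's conformer-free van-der-Waals volume.  The
interaction-level matrix is force-field data: supply it as a TSV; a small
synthetic table stands in here.
"""

import numpy as np
import pandas as pd

import cgline as cg

# synthetic interaction-level matrix (real Martini tables are force-field
# data distributed with the force field itself)
TABLE = pd.DataFrame(
    [[2, 8, 5], [8, 12, 9], [5, 9, 14]],
    index=["C1", "SN4", "TC5"], columns=["C1", "SN4", "TC5"])
table = cg.InteractionTable.from_frame(TABLE)

# a two-resolution solute: Martini beads plus their atomistic fragments
solute = cg.parse_cgsmiles("{[#SN4][#TC5A]}.{#SN4=[$]CCO,#TC5A=[$]CC}")
resolved = cg.resolve_all(solute)

water = cg.parse_cg_graph("[#C1]")          # 1-bead water stand-in
octanol = cg.parse_cg_graph("[#C1][#SN4]")  # 2-bead organic solvent

vector = cg.martini_fingerprint(solute.base, [water, octanol], table,
                                atomic_graph=resolved.molecule)
print("feature vector length:", vector.as_array().size, "(2 x 120 + volume)")
print("water-block pair count:", vector.counts[0].sum(),
      "| organic-block pair count:", vector.counts[1].sum())
nonzero = np.nonzero(vector.counts[1])[0]
print("occupied interaction types (organic block):", nonzero.tolist())
print("solute volume estimate: %.1f A^3" % vector.volume)
# block sums equal n_solute_beads x n_solvent_beads; the volume feature is a
# bond/ring-corrected additive estimate from the atomistic graph.
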