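"""Census of special syntax features over a small molecule library.

Coarse-grained mappings need notation features atomistic strings never use:
shared atoms (squash), virtual particles, linearized rings, mapping weights.
The census reports which entry uses which feature -- the same bookkeeping a
force-field library would run over its full collection.
"""

import cgline as cg

LIBRARY = [
    ("water",   "{[#W]}.{#W=O}"),
    ("pentene", "{[#A][#B]}.{#A=CC=[$],#B=[$]=CCC}"),
    ("toluene", "{[#A]=[#B]}.{#A=[!x]cccc[!y],#B=[!x]c(C)ccc[!y]}"),
    ("glucose-like", "{[#SP4]1[#SP4][#SP1]1.[#TC4]}.{#SP4=[$]CC[$]O,#SP1=[$]CC[$]O}"),
    ("alanine", "{[#P2]}.{#P2=C[C;x=S]C(=O)ON}"),
]

frame = cg.feature_census(
    (name, cg.parse_cgsmiles(string)) for name, string in LIBRARY)
print(frame.astype(int).T.to_string())
print()
print("feature totals over", len(frame), "entries:")
print(frame.sum().to_string())
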