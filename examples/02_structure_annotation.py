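"""Fold an RNA and compute the enhanced structure array.

The structure array refines the dot-bracket into loop context: L/R for the
5'/3' partners of base pairs, H hairpin loop, B bulge, I internal loop,
M multiloop, E exterior (unpaired outside every pair -- flanks, mostly).
"""

from mircleave import annotate, fold, parse_pairs

seq = "GGGAUACGCAGGUCAACGGAUGCGUAUCCCAAACCCUUU"
db = fold(seq, engine="builtin")
ann = annotate(seq, db)

print(seq)
print(ann.dot_bracket)
print(ann.structure_array)
pairs = sorted((i, j) for i, j in parse_pairs(db).items() if i < j)
print(f"\n{len(pairs)} base pairs; first three: {pairs[:3]}")
print(
    "Each unpaired run is classified by its flanking helices; precomputed"
    "\ndot-brackets (e.g. from RNAfold) can be passed to annotate() directly."
)
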