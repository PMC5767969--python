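# Physicochemical residue clusters used for relaxed substrate matching.
# STAND-IN partition (editable): replace with a curated clustering if you
# have one; groups must be disjoint and cover the 20 standard residues.
aliphatic: [A, V, L, I, M]
aromatic: [F, W, Y]
polar: [S, T, N, Q]
acidic: [D, E]
basic: [K, R, H]
cysteine: [C]
glycine: [G]
proline: [P]
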