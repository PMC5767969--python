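# Pocket positions as 1-based indices on the ungapped reference (AlbC-style)
# sequence. PLACEHOLDER defaults (8 positions per pocket): the curated
# reference numbering is not bundled; edit this file to match your
# reference alignment before production use.
P1: [33, 35, 119, 152, 182, 185, 200, 204]
P2: [40, 65, 78, 89, 155, 159, 186, 206]
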