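# Family-level clan assignments for the toy locus.  Clans are the three
# evolutionary groupings of V genes by conserved framework features; the
# assignments here follow the classic mouse family/clan correspondence
# (J558-type distal families in clan 1, Q52-type in clan 2, 7183/36-60-type
# proximal families in clan 3).  Real references differ in detail, which is
# why this lives in a config table rather than in code.
VH1: 1
VH14: 2
VH2: 2
VH3: 3
VH5: 3
VH6: 2
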