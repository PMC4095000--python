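node_id	compartment	position
AGT	blood	upstream
F2	blood	upstream
FGA	blood	downstream
PLG	blood	downstream
ADRB1	plasma_membrane	upstream
AGTR1	plasma_membrane	upstream
TNFR1	plasma_membrane	upstream
HMGCR	cytoplasm	downstream
PTGS2	cytoplasm	downstream
NOS3	cytoplasm	downstream
CASP3	cytoplasm	downstream
PPARG	nucleus	downstream
NFKB1	nucleus	downstream
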