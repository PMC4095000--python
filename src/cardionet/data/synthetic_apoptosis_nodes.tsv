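node_id	compartment	position
TNFR1	plasma_membrane	upstream
FAS	plasma_membrane	upstream
TRADD	cytoplasm	upstream
FADD	cytoplasm	upstream
CASP8	cytoplasm	downstream
BID	cytoplasm	downstream
BCL2	cytoplasm	downstream
BAX	cytoplasm	downstream
CYCS	cytoplasm	downstream
APAF1	cytoplasm	downstream
CASP9	cytoplasm	downstream
CASP3	cytoplasm	downstream
TP53	nucleus	downstream
NFKB1	nucleus	downstream
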