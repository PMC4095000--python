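node_id	compartment	position
AGT	blood	upstream
ACE	blood	upstream
AGTR1	plasma_membrane	upstream
ADRB1	plasma_membrane	upstream
EDNRA	plasma_membrane	upstream
CACNA1C	plasma_membrane	upstream
GNAQ	cytoplasm	upstream
PLCB1	cytoplasm	downstream
ITPR1	cytoplasm	downstream
PRKCA	cytoplasm	downstream
MYLK	cytoplasm	downstream
MYL9	cytoplasm	downstream
ROCK1	cytoplasm	downstream
NOS3	cytoplasm	downstream
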