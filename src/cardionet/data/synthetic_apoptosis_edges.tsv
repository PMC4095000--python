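source_id	target_id	effect
TNFR1	TRADD	activation
FAS	FADD	activation
TRADD	FADD	activation
FADD	CASP8	activation
CASP8	BID	activation
BID	BAX	activation
BCL2	BAX	inhibition
BAX	CYCS	activation
CYCS	APAF1	activation
APAF1	CASP9	activation
CASP9	CASP3	activation
TP53	BAX	activation
NFKB1	CASP8	inhibition
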