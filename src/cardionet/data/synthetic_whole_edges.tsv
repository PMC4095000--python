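source_id	target_id	effect
AGT	AGTR1	activation
F2	FGA	activation
PLG	FGA	inhibition
ADRB1	NOS3	activation
AGTR1	PTGS2	activation
TNFR1	NFKB1	activation
TNFR1	CASP3	activation
NFKB1	PTGS2	activation
PPARG	NFKB1	inhibition
HMGCR	PPARG	activation
NOS3	F2	inhibition
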