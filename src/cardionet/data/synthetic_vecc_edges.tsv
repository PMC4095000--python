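source_id	target_id	effect
AGT	ACE	activation
ACE	AGTR1	activation
AGTR1	GNAQ	activation
ADRB1	GNAQ	activation
EDNRA	GNAQ	activation
GNAQ	PLCB1	activation
PLCB1	ITPR1	activation
ITPR1	PRKCA	activation
CACNA1C	PRKCA	activation
PRKCA	MYLK	activation
MYLK	MYL9	activation
ROCK1	MYL9	activation
NOS3	MYLK	inhibition
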