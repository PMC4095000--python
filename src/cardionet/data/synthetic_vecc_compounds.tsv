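compound_id	name	compound_class	target_id	link_type
WST_VE1	ACE-inhibitor-like western drug	western_drug	ACE	direct
WST_VE2	angiotensin-receptor-blocker-like western drug	western_drug	AGTR1	direct
WST_VE3	beta-blocker-like western drug	western_drug	ADRB1	direct
WST_VE4	calcium-channel-blocker-like western drug	western_drug	CACNA1C	direct
WST_VE5	endothelin-antagonist-like western drug	western_drug	EDNRA	direct
HRB_VE1	contraction-modulating herbal ingredient	herbal_ingredient	NOS3	direct
HRB_VE1	contraction-modulating herbal ingredient	herbal_ingredient	ROCK1	direct
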