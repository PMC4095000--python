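compound_id	name	compound_class	target_id	link_type
HRB_AP1	apoptosis-modulating herbal ingredient 1	herbal_ingredient	CASP3	direct
HRB_AP1	apoptosis-modulating herbal ingredient 1	herbal_ingredient	CASP9	direct
HRB_AP1	apoptosis-modulating herbal ingredient 1	herbal_ingredient	BCL2	direct
HRB_AP1	apoptosis-modulating herbal ingredient 1	herbal_ingredient	BAX	direct
HRB_AP1	apoptosis-modulating herbal ingredient 1	herbal_ingredient	TP53	direct
HRB_AP2	apoptosis-modulating herbal ingredient 2	herbal_ingredient	CYCS	direct
HRB_AP2	apoptosis-modulating herbal ingredient 2	herbal_ingredient	APAF1	direct
HRB_AP2	apoptosis-modulating herbal ingredient 2	herbal_ingredient	NFKB1	direct
HRB_AP2	apoptosis-modulating herbal ingredient 2	herbal_ingredient	CASP8	direct
WST_AP1	apoptosis-adjacent western drug	western_drug	BCL2	direct
WST_AP1	apoptosis-adjacent western drug	western_drug	TP53	direct
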