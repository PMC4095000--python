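compound_id	name	compound_class	target_id	link_type
WST_WH1	anticoagulant-like western drug	western_drug	F2	direct
WST_WH2	fibrinolytic-era western drug	western_drug	FGA	direct
WST_WH3	beta-blocker-like western drug	western_drug	ADRB1	direct
WST_WH4	angiotensin-receptor-blocker-like western drug	western_drug	AGTR1	direct
HRB_WH1	blood-acting herbal ingredient	herbal_ingredient	PLG	direct
HRB_WH2	intracellular herbal ingredient 1	herbal_ingredient	PTGS2	direct
HRB_WH2	intracellular herbal ingredient 1	herbal_ingredient	HMGCR	direct
HRB_WH3	intracellular herbal ingredient 2	herbal_ingredient	PPARG	direct
HRB_WH3	intracellular herbal ingredient 2	herbal_ingredient	CASP3	direct
HRB_WH3	intracellular herbal ingredient 2	herbal_ingredient	NOS3	direct
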