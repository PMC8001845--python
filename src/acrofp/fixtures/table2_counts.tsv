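species	clade	gfp_cfp	rfp	chrp	fp_total
Astreopora_myriophthalma	Astreopora	2	0	0	2
Montipora_efflorescens	Montipora	1	0	1	2
Montipora_cactus	Montipora	1	1	0	2
Acropora_tenuis	I	4	3	2	9
Acropora_yongei	I	8	3	7	18
Acropora_intermedia	II	9	3	6	18
Acropora_gemmifera	II	6	1	2	9
Acropora_awi	II	4	6	1	11
Acropora_florida	II	7	5	2	14
Acropora_digitifera	III	9	2	7	18
Acropora_nasuta	III	7	1	8	16
Acropora_microphthalma	III	8	4	1	13
Acropora_acuminata	III	7	2	5	14
Acropora_echinata	IV	7	4	1	12
Acropora_muricata	IV	4	5	4	13
Acropora_selago	IV	11	0	4	15
Acropora_cytherea	IV	9	3	5	17
Acropora_hyacinthus	IV	11	1	4	16
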