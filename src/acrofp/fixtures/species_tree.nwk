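# Acroporid backbone species tree: 18 tips, four Acropora clades (I-IV),
# Montipora sister to Acropora, Astreopora basal.  Branch lengths are
# relative time units (all tips at depth 1.2); within-clade branching order
# is not fully constrained by the published figure and the placements of
# (digitifera,nasuta)/(microphthalma,acuminata) pairings and the clade I+II
# vs III+IV arrangement are conventional choices.
(Astreopora_myriophthalma:1.2,((Montipora_cactus:0.5,Montipora_efflorescens:0.5)Montipora_anc:0.55,(((Acropora_tenuis:0.4,Acropora_yongei:0.4)CladeI_anc:0.25,(Acropora_intermedia:0.45,(Acropora_gemmifera:0.3,(Acropora_awi:0.2,Acropora_florida:0.2)CladeII_af:0.1)CladeII_core:0.15)CladeII_anc:0.1)CladeI_II_anc:0.15,(((Acropora_digitifera:0.2,Acropora_nasuta:0.2)CladeIII_dn:0.2,(Acropora_microphthalma:0.2,Acropora_acuminata:0.2)CladeIII_ma:0.2)CladeIII_anc:0.15,(Acropora_echinata:0.45,(Acropora_muricata:0.35,(Acropora_selago:0.25,(Acropora_cytherea:0.2,Acropora_hyacinthus:0.2)CladeIV_ch:0.05)CladeIV_sch:0.1)CladeIV_core:0.1)CladeIV_anc:0.1)CladeIII_IV_anc:0.15)Acropora_ancestor:0.35)Montipora_Acropora_anc:0.15)Acroporidae_root;
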