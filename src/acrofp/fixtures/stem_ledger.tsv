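record	class	node	dups	losses
root_copies	total	Acroporidae_root	5	.
root_copies	GFP/CFP	Acroporidae_root	5	.
root_copies	RFP	Acroporidae_root	0	.
root_copies	ChrP	Acroporidae_root	0	.
branch	total	Acropora_ancestor	11	0
branch	GFP/CFP	Acropora_ancestor	4	0
branch	RFP	Acropora_ancestor	3	0
branch	ChrP	Acropora_ancestor	4	0
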