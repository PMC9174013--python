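String_node	Gene_name	String_ID	Freq
TFDP1	TFDP1	ENSP00000364519	6
KRAS	KRAS	ENSP00000256078	4
LMNB1	LMNB1	ENSP00000261366	4
MET	MET	ENSP00000317272	4
MYBL2	MYBL2	ENSP00000217026	4
CDC25A	CDC25A	ENSP00000303706	3
E2F5	E2F5	ENSP00000398124	3
HMGA1	HMGA1	ENSP00000399888	3
HMGA2	HMGA2	ENSP00000437621	3
CBFB	CBFB	ENSP00000415151	2
CBX3	CBX3	ENSP00000336687	2
CDC7	CDC7	ENSP00000393139	2
IGF2BP3	IGF2BP3	ENSP00000258729	2
KIF11	KIF11	ENSP00000260731	2
PDGFB	PDGFB	ENSP00000330382	2
SMC1A	SMC1A	ENSP00000323421	2
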