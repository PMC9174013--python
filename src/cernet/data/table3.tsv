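DEcircRNA	DEmiRNA	DEmRNA
hsa_circ_0000043	has-miR-326	KRAS
hsa_circ_0000384	has-miR-326	KRAS
hsa_circ_0000384	has-miR-23b-3p	MET
hsa_circ_0000384	has-miR-23b-3p	LMNB1
hsa_circ_0000384	has-miR-30a-5p	CBFB
hsa_circ_0000384	has-miR-30a-5p	CDC7
hsa_circ_0000384	has-miR-30a-5p	KIF11
hsa_circ_0000384	has-miR-30a-5p	MYBL2
hsa_circ_0000384	has-miR-30a-5p	CBX3
hsa_circ_0000384	has-miR-30a-5p	TFDP1
hsa_circ_0000384	has-miR-30c-5p	CBFB
hsa_circ_0000384	has-miR-30c-5p	CDC7
hsa_circ_0000384	has-miR-30c-5p	KIF11
hsa_circ_0000384	has-miR-30c-5p	MYBL2
hsa_circ_0000384	has-miR-30c-5p	CBX3
hsa_circ_0000384	has-miR-30c-5p	TFDP1
hsa_circ_0000384	has-let-7c-5p	HMGA1
hsa_circ_0000384	has-let-7c-5p	HMGA2
hsa_circ_0000384	has-let-7c-5p	E2F5
hsa_circ_0000384	has-let-7c-5p	IGF2BP3
hsa_circ_0000384	has-let-7c-5p	CDC25A
hsa_circ_0000384	has-let-7c-5p	SMC1A
hsa_circ_0000384	has-let-7c-5p	PDGFB
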