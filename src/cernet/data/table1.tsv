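circRNA_ID	Position	Genomic_length	Strand	Best_transcript	Gene_symbol	Regulation
hsa_circ_0003458	chr9:115013208-115060196	46988	-	NM_001163790	PTBP3	Up
hsa_circ_0004273	chr17:60111147-60112969	1822	-	NM_005121	MED13	Up
hsa_circ_0006308	chr5:38991050-39021238	30188	-	NM_152756	RICTOR	Up
hsa_circ_0007290	chrX:44383247-44386611	3364	-	NM_173794	FUNDC1	Up
hsa_circ_0023942	chr11:85733409-85742653	9244	-	NM_007166	PICALM	Up
hsa_circ_0000043	chr1:31465236-31468067	2831	-	NM_014676	PUM1	Up
hsa_circ_0000384	chr12:27867712-27877119	9407	+	NM_001190864	MRPS35	Up
hsa_circ_0007108	chrX:24190831-24197887	7056	+	NM_001178085	ZFX	Down
hsa_circ_0003855	chr12:12672795-12674397	1602	-	NM_030640	DUSP16	Down
hsa_circ_0009964	chr1:12335881-12338095	2214	+	NM_015378	VPS13D	Down
hsa_circ_0083444	chr8:17601112-17613470	12358	-	NM_001001924	MTUS1	Down
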