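snp_id	Caucasus	EuropeanRussia	WestSiberia	pooled	hirisplex	rsid	gene
chr15:28356859_C_T	2	2	2	3	rs1129038	rs1129038	HERC2
chr15:28365618_A_G	2	2	2	3	rs12913832	rs12913832	HERC2
chr15:28392261_G_A	2	2	0	3		rs12898729	HERC2
chr15:28410491_C_T	2	2	0	3		rs12916300	HERC2
chr15:28495956_A_G	2	2	0	3		rs12912427	HERC2
chr15:28562998_T_C	0	1	0	2		rs1614575	HERC2
chr20:39272620_A_G	0	1	0	2		rs4812447	Intergene spacer
chr1:119406130_C_T	0	0	0	2		rs1779446	Intergene spacer
chr1:3331899_A_G	0	0	0	2		rs1999528	PRDM16
chr15:28145024_T_C	0	0	0	2		rs2871886	OCA2
chr15:28364059_A_G	0	0	0	2		rs7494942	HERC2
chr15:28380518_T_A	0	0	0	2		rs4778249	HERC2
chr15:28383565_T_C	0	0	0	2		rs7403279	HERC2
chr15:28513364_T_C	0	0	0	2	rs916977	rs916977	HERC2
chr15:28530182_C_T	0	0	0	2	rs1667394	rs1667394	HERC2
chr15:28566122_A_G	0	0	0	2		rs751089833	HERC2
chr19:7570978_T_C	0	0	0	2		rs685034	C19orf45
chr3:189429301_G_T	0	0	0	2		rs6804480	TP63
chr6:45136347_G_A	0	0	0	2		rs1324530	SUPT3H
chrX:66405249_C_T	0	0	0	2		rs34191540	Intergene spacer
chr10:87576467_C_T	0	0	0	1		rs7923503	GRID1
chr14:92909309_T_C	0	0	0	1		rs12588868	SLC24A4
chr15:28419048_T_G	0	0	0	1		rs35946704	HERC2
chr17:9107969_G_A	0	0	0	1		rs17742781	NTN1
chr19:7578733_A_T	0	0	0	1		rs586243	ZNF358
chr3:189552236_T_C	0	0	0	1		rs7653443	MIR944
chr3:33035542_T_C	0	0	0	1		rs4586761	GLB1
chr3:33111182_T_G	0	0	0	1		rs72856153	GLB1
chr3:54251172_G_A	0	0	0	1		rs11283625	CACNA2D3
chr3:54636061_G_A	0	0	0	1		rs34983676	CACNA2D3
chr4:87847613_T_G	0	1	0	1		rs10022539	LOC100506746
chr4:87851083_C_T	0	0	0	1		rs72667724	LOC100506746
chr5:60947483_A_G	0	0	0	1		rs1501841	C5orf64
chr5:73959526_A_G	0	0	0	1		rs2454846	HEXB
chr6:45419110_C_G	0	0	0	1		rs2820339	RUNX2
chr7:42032565_C_T	0	0	0	1		rs2237427	GLI3
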