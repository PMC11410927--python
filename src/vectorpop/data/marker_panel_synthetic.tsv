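# synthetic surveillance panel: real gene/substitution names, placeholder coordinates
gene	label	chrom	strand	codon_number	pos1	pos2	pos3	ref_codon
Vgsc	L995F	2L	+	995	2422651	2422652	2422653	TTA
Vgsc	L995S	2L	+	995	2422651	2422652	2422653	TTA
Vgsc	R254K	2L	+	254	2420428	2420429	2420430	AGA
Vgsc	N1570Y	2L	+	1570	2424376	2424377	2424378	AAT
Rdl	A296G	2L	+	296	25429235	25429236	25429237	GCA
Rdl	A296S	2L	+	296	25429235	25429236	25429237	GCA
Rdl	T345M	2L	+	345	25429382	25429383	25429384	ACG
Ace1	G280S	2R	-	280	3492074	3492073	3492072	GGC
Cyp4j5	L43F	2L	+	43	25635973	25635974	25635975	TTA
Cyp6p4	L161F	2R	-	161	28497967	28497966	28497965	CTT
Cyp6p4	I236M	2R	-	236	28497742	28497741	28497740	ATA
Cpr	K75N	X	+	75	8841504	8841505	8841506	AAA
Cpr	T319N	X	+	319	8842236	8842237	8842238	ACT
Cpr	A583S	X	+	583	8843028	8843029	8843030	GCT
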