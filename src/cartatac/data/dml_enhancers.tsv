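enhancer_peak	probe	delta_beta	log2fc	fdr	target_genes
chr1:19398124-19398841	cg06360604	-0.177	1.194	0.003	AKR7A2;AKR7A3;CAPZB;PQLC2
chr16:66511371-66512170	cg02934719	-0.168	0.827	0.021	BEAN1;TK2
chr11:74025533-74026295	cg01117339	-0.164	0.623	0.037	COA4;RAB6A;UCP2
chr1:85606965-85607684	cg00418071	-0.157	1.214	0.001	CYR61;DDAH1;ZNHIT6;SYDE2
chr4:158809913-158811140	cg11637968	-0.218	0.878	0.032	ETFDH;FAM198B;FNIP2;PPID;C4orf46
chr5:32767956-32768626	cg26647771	-0.198	0.924	0.010	GOLPH3;NPR3;TARS
chr1:226708432-226710048	cg04503570	-0.166	0.500	0.046	PSEN2
chr2:1720779-1722443	cg08216099	-0.193	0.732	0.016	PXDN
chr10:119523073-119524950	cg18591136	-0.152	0.508	0.040	RGS10
chr6:168412123-168412714	cg26379705	-0.174	0.736	0.009	SMOC2
chr6:146850220-146851275	cg18291422	-0.184	0.960	0.012	STXBP5
chr8:81688679-81689538	cg04491064	0.164	-0.959	0.046	CHMP4C
chr12:124700740-124701544	cg04658679	0.160	-0.514	0.030	FAM101A;UBC
chr4:26412447-26413348	cg22992279	0.159	-0.737	0.028	RBPJ
chr11:35344856-35345647	cg13971030	0.157	-0.656	0.038	SLC1A2
chr12:132846887-132848225	cg21232015	0.151	-0.615	0.038	ZNF10;ZNF268;ZNF605;ZNF84;GOLGA3;ANKLE2;CHFR
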