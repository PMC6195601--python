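enhancer_peak	proxy_snp	lead_snp	r2	gwas_p	phenotype	population	log2fc	fdr	target_genes
chr7:32611048-32612186	rs10807862	rs7805536	0.8	4.4e-8	OA	EUR	-0.96	0.01	ZNRF2P1;DPY19L1P1;AVL9;LSM5
chr7:32616344-32617105	rs10951345	rs7805536	0.8	4.4e-8	OA	EUR	-0.77	0.03	DPY19L1P1;AVL9
chr10:119370132-119371726	rs17098787	rs11198893	0.9	9.0e-6	OA (knee and hip)	EUR	-0.59	0.02	RP11-215A21.2
chr7:44238166-44238952	rs67391165	rs3757837	1.0	8.0e-10	OA (hip)	EUR	0.62	0.03	MYL7;YKT6
chr8:125503356-125504061	rs7832357	rs4512391	1.0	1.1e-6	OA (knee and hip)	EUR	-0.54	0.04	NA
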