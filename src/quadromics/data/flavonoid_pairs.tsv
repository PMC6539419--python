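gene_id	gene_name	gene_log2fc	metabolite_id	metabolite_log2fc	pcc
Gh_A10G0884	WUS	2.12	pme3268	2.65	-1
Gh_A02G0853	CLV1	3.00	pme2898	-18.40	1
Gh_A02G0853	CLV1	3.00	pme0200	12.00	-1
Gh_A02G0853	CLV1	3.00	pme3268	2.65	-1
Gh_A02G0853	CLV1	3.00	pme2459	1.72	-1
Gh_A02G0853	CLV1	3.00	pme0202	3.99	-1
Gh_D01G0448	CUC2	2.77	pme2459	1.72	-1
Gh_D01G0448	CUC2	2.77	pme3212	2.73	-1
Gh_D02G0017	SCW	2.55	pme2898	-18.40	-1
Gh_D02G0017	SCW	2.55	pme0200	12.00	1
Gh_D02G0017	SCW	2.55	pme3268	2.65	1
Gh_D02G0017	SCW	2.55	pme2459	1.72	1
Gh_A12G0710	SHR	1.90	pmb0605	-2.79	-1
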