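gene_id	gene_name	gene_log2fc	metabolite_id	metabolite_log2fc	pcc
Gh_A08G2008	BBM	6.54	pmc0066	13.65	-1
Gh_A08G2008	BBM	6.54	pmd0023	7.08	-1
Gh_A08G2008	BBM	6.54	pmb2948	11.31	-1
Gh_A08G2008	BBM	6.54	pmb0981	15.26	-1
Gh_A08G2008	BBM	6.54	pme3960	16.20	-1
Gh_A08G2008	BBM	6.54	pme1181	4.10	-1
Gh_A08G2008	BBM	6.54	pme1175	6.54	-1
Gh_A08G2008	BBM	6.54	pme3835	14.00	-1
Gh_A08G2008	BBM	6.54	pme1296	7.10	-1
Gh_D06G1184	SERK1	1.25	pmc0066	13.65	1
Gh_D06G1184	SERK1	1.25	pmd0023	7.08	1
Gh_D06G1184	SERK1	1.25	pmb2948	11.31	1
Gh_D06G1184	SERK1	1.25	pmb0981	15.26	1
Gh_D06G1184	SERK1	1.25	pmb2684	15.50	1
Gh_D06G1184	SERK1	1.25	pme3960	16.20	1
Gh_D06G1184	SERK1	1.25	pme1181	4.10	1
Gh_D06G1184	SERK1	1.25	pme1175	6.54	1
Gh_D06G1184	SERK1	1.25	pme3835	14.00	1
Gh_D06G1184	SERK1	1.25	pme1296	7.10	1
Gh_D13G1387	LEC1	6.44	pmc0066	13.65	1
Gh_D13G1387	LEC1	6.44	pmd0023	7.08	1
Gh_D13G1387	LEC1	6.44	pmb2948	11.31	1
Gh_D13G1387	LEC1	6.44	pmb0981	15.26	1
Gh_D13G1387	LEC1	6.44	pme3960	16.20	1
Gh_D13G1387	LEC1	6.44	pme3835	14.00	1
Gh_D07G0476	ARF2	1.89	pmc0066	13.65	1
Gh_D07G0476	ARF2	1.89	pmd0023	7.08	1
Gh_D07G0476	ARF2	1.89	pmb2948	11.31	1
Gh_D07G0476	ARF2	1.89	pmb0981	15.26	1
Gh_D07G0476	ARF2	1.89	pme3960	16.20	1
Gh_D07G0476	ARF2	1.89	pme1181	4.10	1
Gh_D07G0476	ARF2	1.89	pme3835	14.00	1
Gh_A12G0910	AGL15	6.47	pmc0066	13.65	-1
Gh_A12G0910	AGL15	6.47	pmd0023	7.08	-1
Gh_A12G0910	AGL15	6.47	pmb2948	11.31	-1
Gh_A12G0910	AGL15	6.47	pmb0981	15.26	-1
Gh_A12G0910	AGL15	6.47	pme3960	16.20	-1
Gh_A12G0910	AGL15	6.47	pme1181	4.10	-1
Gh_A12G0910	AGL15	6.47	pme1175	6.54	-1
Gh_A12G0910	AGL15	6.47	pme3835	14.00	-1
Gh_A12G0910	AGL15	6.47	pme1296	7.10	-1
Gh_D07G0323	AGP1	5.93	pmc0066	13.65	1
Gh_D07G0323	AGP1	5.93	pmd0023	7.08	1
Gh_D07G0323	AGP1	5.93	pmb2948	11.31	1
Gh_D07G0323	AGP1	5.93	pmb0981	15.26	1
Gh_D07G0323	AGP1	5.93	pmb2684	15.50	1
Gh_D07G0323	AGP1	5.93	pme3960	16.20	1
Gh_D07G0323	AGP1	5.93	pme1181	4.10	1
Gh_D07G0323	AGP1	5.93	pme3835	14.00	1
Gh_A12G1076	GLP2	-1.13	pmb2684	15.50	-1
Gh_A12G1076	GLP2	-1.13	pme1181	4.10	-1
Gh_A09G1557	AGO1	1.19	pmc0066	13.65	1
Gh_A09G1557	AGO1	1.19	pmd0023	7.08	1
Gh_A09G1557	AGO1	1.19	pmb2948	11.31	1
Gh_A09G1557	AGO1	1.19	pmb0981	15.26	1
Gh_A09G1557	AGO1	1.19	pmb2684	15.50	1
Gh_A09G1557	AGO1	1.19	pme3960	16.20	1
Gh_A09G1557	AGO1	1.19	pme1181	4.10	1
Gh_A09G1557	AGO1	1.19	pme3835	14.00	1
Gh_D05G1937	AMY1	-4.34	pmc0066	13.65	-1
Gh_D05G1937	AMY1	-4.34	pmd0023	7.08	-1
Gh_D05G1937	AMY1	-4.34	pmb2948	11.31	-1
Gh_D05G1937	AMY1	-4.34	pmb0981	15.26	-1
Gh_D05G1937	AMY1	-4.34	pmb2684	15.50	-1
Gh_D05G1937	AMY1	-4.34	pme3960	16.20	-1
Gh_D05G1937	AMY1	-4.34	pme1181	4.10	-1
Gh_D05G1937	AMY1	-4.34	pme3835	14.00	-1
Gh_A12G0504	LTP2	3.58	pmc0066	13.65	1
Gh_A12G0504	LTP2	3.58	pmd0023	7.08	1
Gh_A12G0504	LTP2	3.58	pmb2948	11.31	1
Gh_A12G0504	LTP2	3.58	pmb0981	15.26	1
Gh_A12G0504	LTP2	3.58	pmb2684	15.50	1
Gh_A12G0504	LTP2	3.58	pme3960	16.20	1
Gh_A12G0504	LTP2	3.58	pme1181	4.10	1
Gh_A12G0504	LTP2	3.58	pme3835	14.00	1
Gh_A12G0504	LTP2	3.58	pmb4344	14.40	1
Gh_D12G0517	LTP2-like	3.03	pmc0066	13.65	1
Gh_D12G0517	LTP2-like	3.03	pmb0981	15.26	1
Gh_D12G0517	LTP2-like	3.03	pme3960	16.20	1
Gh_D12G0517	LTP2-like	3.03	pme1181	4.10	1
Gh_D12G0517	LTP2-like	3.03	pmb4344	14.40	1
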