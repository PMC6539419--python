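feature_id	name	feature_class	fc	log2fc_printed	status
pmb0981	Adenosine 5'-monophosphate	Nucleotide and its derivates	3.92e4	15.3	up
pmb2684	Cyclic AMP	Nucleotide and its derivates	4.79e4	15.5	up
pmb2948	Adenosine 3'-monophosphate	Nucleotide and its derivates	2.54e3	11.3	up
pmb4344	Guanosine 5'-monophosphate	Nucleotide and its derivates	2.19e4	14.4	up
pmc0066	2'-Deoxyinosine-5'-monophosphate	Nucleotide and its derivates	1.29e4	13.7	up
pmd0023	Adenosine	Nucleotide and its derivates	1.36e2	7.08	up
pme1175	Guanosine	Nucleotide and its derivates	93.1	6.54	up
pme1181	Deoxyguanosine	Nucleotide and its derivates	17.1	4.10	up
pme1296	Xanthosine	Nucleotide and its derivates	1.37e2	7.10	up
pme3835	Guanosine 3',5'-cyclic monophosphate	Nucleotide and its derivates	1.64e4	14.0	up
pme3960	Deoxyadenosine	Nucleotide and its derivates	7.32e4	16.2	up
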