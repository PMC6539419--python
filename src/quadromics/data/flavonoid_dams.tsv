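feature_id	name	feature_class	fc	log2fc_printed	status
pme1580	Eriodictyol	Flavanone	4.17	2.06	up
pme2319	Hesperetin	Flavanone	2.43	1.28	up
pmb0605	Apigenin 7-O-glucoside (Cosmosiin)	Flavone	0.145	-2.79	down
pme0088	Luteolin	Flavone	3.56	1.83	up
pme2459	Luteolin 7-O-glucoside (Cynaroside)	Flavone	3.30	1.72	up
pme3300	Tricetin	Flavone	2.60	1.38	up
pme0199	Quercetin	Flavonol	56.9	5.83	up
pme0200	Kaempferol	Flavonol	4.09e3	12.0	up
pme0202	Quercetin 3-O-rutinoside (Rutin)	Flavonol	15.9	3.99	up
pme1478	Myricetin	Flavonol	44.2	5.46	up
pme1521	Dihydroquercetin (Taxifolin)	Flavonol	4.60	2.20	up
pme2898	Dihydromyricetin	Flavonol	2.92e-6	-18.4	down
pme3212	Quercetin 3-O-glucoside (Isotrifoliin)	Flavonol	6.63	2.73	up
pme3268	Kaempferol 3-O-galactoside (Trifolin)	Flavonol	6.26	2.65	up
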