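rank	protein_id	alias	snr_minus	snr_plus	calling_score_printed	annotation
1	EentC	EntC	152.91	36.08	4.24	isochorismate synthase 1
2	YgdK	YgdK	147.60	56.78	2.60	predicted Fe-S metabolism protein
3	RibD	RibD	117.46	42.31	2.78	5-amino-6-(5-phosphoribosylamino)uracil reductase
4	YbiJ	YbiJ	109.97	34.14	3.22	predicted protein
5	Exo	Exo	101.99	23.46	4.35	Uncharacterized exonuclease xni
6	DeoA	DeoA	98.69	19.72	5.01	Thymidine phosphorylase
7	MaoC	MaoC	87.76	29.99	2.93	fused aldehyde dehydrogenase/enoyl-CoA hydratase
8	SbcB	SbcB	86.40	30.07	2.87	Exodeoxyribonuclease I
9	HolC	HolC	75.41	28.14	2.68	DNA polymerase III subunit chi
10	DnaC	DnaC	70.21	23.74	2.96	DNA replication protein dnaC
11	YcaK	YcaK	68.36	7.63	8.96	conserved protein
12	YbaJ	YbaJ	67.09	19.20	3.49	predicted protein
13	YkgD	YkgD	62.64	10.62	5.90	predicted DNA-binding transcriptional regulator
14	Edd	Edd	62.55	8.40	7.45	6-phosphogluconate dehydratase
15	FimH	FimH	49.48	17.65	2.80	minor component of type 1 fimbriae
16	AroK	AroK	47.97	8.19	5.86	shikimate kinase I
17	TalB	TalB	47.56	3.94	12.08	transaldolase B
18	WzxC	WzxC	39.35	15.32	2.57	colanic acid exporter
19	SurA	SurA	32.55	8.06	4.04	peptidyl-prolyl cis-trans isomerase (PPIase); Chaperone surA
20	YifC	YifC	33.63	12.86	2.62	Lipopolysaccharide biosynthesis protein
21	YbdK	YbdK	25.22	6.95	3.63	Carboxylate-amine ligase ybdK
22	HisP	HisP	28.36	10.06	2.82	Histidine transport ATP-binding protein
23	YdiD	YdiD	20.33	2.01	10.11	Short chain fatty acid CoA ligase
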