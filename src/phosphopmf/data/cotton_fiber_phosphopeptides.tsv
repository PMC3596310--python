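spot	category	protein_name	accession	peptide	ion_score	start	end	p3db_known
8	Cytoskeleton	Beta-tubulin 19	AF484959	FPGQLNS^PDLRK	19.32	242	252	1
9	Cytoskeleton	Beta-tubulin 1	AF484959	FPGQLNS^PDLRK	30.87	242	252	1
69	Cytoskeleton	Beta-tubulin 19	AF484959	FPGQLNS^PDLRK	23.61	242	252	1
93	Cytoskeleton	annexin 1	ES808831	VPAHVPAPS^PEDAEQLR	38.7	6	21	0
110	Cytoskeleton	Actin-depolymerizing factor	DW517437	LGEPSQS^PYDDFTASLPADEC^CamR	31.79	46	66	0
110	Cytoskeleton	Actin-depolymerizing factor	DW517437	IFFIAWSPDTS^PR	70.66	85	96	0
19	Redox Homeostasis	NADP-dependent oxidoreductase P2	ES825728	NLY^PLSC^CamDPYMR	21.29	48	58	0
13	Redox Homeostasis	Catalase isozyme 1	X52135	HAEMFPIPPAVC^CamT^PGR	41.03	402	416	1
154	Redox Homeostasis	Glutathione S-transferase	ES825910	KHVSAWWDDIS^PSRPSWQK	27.79	189	206	1
156	Redox Homeostasis	GSH-dependent dehydroascorbate reductase1	ES798668	KWTVPESLT^PNVR	27.68	169	180	0
162	Structural and Storage Components	MLP-like protein 31	CD485625	EVVEAVDPDKNLVT^PFR	52.95	74	89	1
48	One-carbon Metabolism	5-methyltetrahydropteroyltriglutamate--homocysteine methyltransferase	ES832618	WAVHS^PFR	15.9	616	622	0
49	One-carbon Metabolism	5-methyltetrahydropteroyltriglutamate--homocysteine methyltransferase	ES832618	WAVHS^PFR	17.18	616	622	0
49	One-carbon Metabolism	5-methyltetrahydropteroyltriglutamate--homocysteine methyltransferase	ES832618	YGAGIGPGVYDIHS^PPR	91.31	679	694	1
77	One-carbon Metabolism	S-adenosylmethionine synthetase 1	EF643509	FVIGGPHGDAGLT^PGR	78.06	238	252	0
66	Energy Metabolism	Dihydrolipoyl dehydrogenase	ES815537	LGSEVTVVEFAPDIVPS^PMDAEIR	116.46	238	260	0
117	Energy Metabolism	Enolase	AY297757	AAVPSGASTGIY^PEALELR	38.48	36	53	1
135	Energy Metabolism	Enolase	AY297757	AAVPSGASTGIY^PEALELR	32.47	36	53	1
135	Energy Metabolism	Enolase	AY297757	Y^PNQLLR	21.29	417	422	0
204	Energy Metabolism	Enolase	AY297757	AAVPSGASTGIY^PEALELR	67.95	36	53	1
233	Energy Metabolism	Enolase	AY297757	AAVPSGASTGIY^PEALELR	27.03	36	53	1
97	Signal Transduction	14-3-3 like protein	CO123672	DS^PTLIMQLLR	36.9	222	231	0
60	Transport	Putative importin alpha protein	ES809347	GKPPT^PPFEQVKPALPVLR	112.55	235	252	1
194	Transport	Putative importin alpha protein	ES809347	GKPPT^PPFEQVKPALPVLR	71.48	235	252	1
65	Transport	Plasma ATP synthase subunit beta	ES810918	T^PDHFLPIHR	20.58	186	194	0
201	Transport	Plasma ATP synthase subunit beta	ES810918	NLQDIIAILGMDELS^PEDDKLTVAR	29.74	461	484	1
200	Transport	Rab GDP dissociation inhibitor	ES843277	LYAES^PLAR	27.2	210	217	0
200	Transport	Rab GDP dissociation inhibitor	ES843277	YLDEPALDT^PVKR	28.21	196	207	1
160	Protein Folding and Assembly	Peptidyl-prolyl cis-trans isomerase	ES800916	VFFDMT^PIGGQPAGR	57.52	7	20	0
112	Protein Folding and Assembly	Peptidyl-prolyl cis-trans isomerase	ES800916	VFFDMT^PIGGQPAGR	57.64	7	20	0
112	Protein Folding and Assembly	Peptidyl-prolyl cis-trans isomerase	ES800916	IVMELFADC^CamT^PPR	24.34	21	32	0
112	Protein Folding and Assembly	Peptidyl-prolyl cis-trans isomerase	ES800916	VIPNFMC^CamQGGDFT^PAGNGTGGESIYGSK	44.69	64	90	1
118	Protein Folding and Assembly	26S proteasome ATPase subunit RPT5a	CO081538	T^PMLELLNQLDGFSSDER	30.55	293	309	0
180	Protein Folding and Assembly	Heat shock protein 70	ES808708	SKFES^PLVNHLIER	39.77	347	359	0
187	Protein Folding and Assembly	T-complex protein 1, theta subunit	ES797476	LSQPKPDDLGFVDS^PISVEEIGGSR	31.02	337	360	0
189	Protein Folding and Assembly	Chaperonin CPN60, mitochondrial	ES827612	MISTSEEIAQVGTIS^PANGER	69.24	168	187	0
98	Non-Energy Carbohydrate Metabolism	UDP-L-rhamnose synthase	EE592948	LC^CamES^PQGIDYEYGSGR	29.65	31	45	1
98	Non-Energy Carbohydrate Metabolism	UDP-L-rhamnose synthase	EE592948	TNVVGT^PLTLADVC^CamR	34.36	89	102	0
125	Non-Energy Carbohydrate Metabolism	Putative transketolase	ES817011	ALPTYTPES^PPADATR	26.23	424	438	1
30	Lipid and Secondary Metabolism	NADPH-dependent mannose 6-phosphate reductase	ES808353	SIGIS^PNYDIFLTR	122.49	156	168	0
55	Lipid and Secondary Metabolism	Betaine-aldehyde dehydrogenase	AY461804	GKDWAT^PAPGAVR	47.36	63	74	0
89	Lipid and Secondary Metabolism	Phenylcoumaran benzylic ether reductase-like protein	ABN12322	FFPS^PEFGMDVDKNNAVEPAK	89.16	108	127	1
84	Amino Acid Metabolism	Phosphoserine aminotransferase	ES820382	NVGPS^PGVC^CamIVIVR	20.44	256	268	0
134	Amino Acid Metabolism	Ketol-acid reductoisomerase	DW226411	GVSFMVDNC^CamSTT^PAR	20.46	500	513	0
212	Amino Acid Metabolism	Glutamine synthetase	EU223825	IIAEYIWIGGS^PGMDLR	51.58	19	34	0
137	Amino Acid Metabolism	Serine hydroxymethyltransferase	ACJ11726	ISAVSIFFETMPY^PR	28.57	186	199	0
1	Unknown	TIM-barrel enzyme family protein	CO129426	IHIHNAQVS^PLMR	51.68	24	35	0
1	Unknown	TIM-barrel enzyme family protein	CO129426	QLES^PIGFSGVQNFPTVGLFDGNFR	35.94	285	308	0
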