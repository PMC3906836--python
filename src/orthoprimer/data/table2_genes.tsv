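code	gene	description	n_species	aln_length	n_informative	min_changes	published_genomes	is_protein
SA	SAH1	Homocysteine hydrolase	38	279	84	271	18	1
GI	PGI1	Phosphoglucose isomerase	39	182	85	306	18	1
PG	PGK1	Phosphoglycerate kinase	36	268	97	391	17	1
DE	ADE6	Formylglycinamidine ribonucleotide synthetase	31	158	100	362	18	1
ME	MET6	Methionine synthase	36	160	65	208	18	1
AT	ATP2	ATP synthase	40	223	45	160	18	1
GC	GCD11	Translation initiation factor	30	219	79	264	18	1
FS	FAS1	Fatty acid synthetase	36	121	61	230	18	1
PA	PDA1	Pyruvate dehydrogenase	35	125	51	159	18	1
VM	VMA2	ATPase	38	180	28	67	18	1
EC	ECM17	Sulphite reductase	37	197	117	484	18	1
OL	POL2	DNA polymerase	36	150	83	327	18	1
LT1	GLT1	Glutamate synthase	42	149	89	417	18	1
LT2	GLT1	Glutamate synthase	32	176	103	369	17	1
18S	18S	18S rRNA gene	30	1993	336	906		0
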