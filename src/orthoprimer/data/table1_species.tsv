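clade	code	cbs_id	species	n_fragments	SA	GI	PG	DE	ME	AT	GC	FS	PA	VM	EC	OL	LT1	LT2
A	C31	6740	Lipomyces (Babjevia) anomalus	9	1	1	0	1	1	1	0	0	1	0	1	0	1	1
A	C38	7251	Lipomyces (Zygozyma) suomiensis	10	1	1	0	1	1	1	0	1	1	1	0	1	0	1
A	C17	2514	Lipomyces kononenkoae	7	1	0	0	0	0	1	0	0	0	1	1	1	1	1
B	C30	6739	Candida sorbophila	11	1	1	1	1	1	1	0	1	1	0	1	0	1	1
B	C04	521.75	Blastobotrys aristata	8	1	1	1	0	0	1	0	0	1	1	0	1	1	0
B	C19	2594	Nadsonia fulvescens	10	1	1	1	1	0	0	1	1	1	1	1	0	1	0
B	C10	765.70	Dipodascus tetrasperma	12	1	1	1	0	1	1	0	1	1	1	1	1	1	1
B	C09	749.85	Dipodascus ambrosiae	7	1	1	0	0	1	1	0	0	0	1	1	0	1	0
B	C12	817.71	Dipodascus armillariae	7	1	0	0	0	0	1	1	0	0	1	1	0	1	1
B	C01	179.60	Galactomyces reessii	11	0	1	1	1	1	1	0	1	0	1	1	1	1	1
D	C40	8139	Dekkera anomala	4	0	0	1	1	0	1	0	0	0	0	0	0	1	0
D	C37	7119	Pichia deserticola	10	0	1	0	0	1	0	1	1	1	1	1	1	1	1
D	C32	6929	Pichia pseudocactophila	13	1	1	1	1	1	1	1	1	1	0	1	1	1	1
D	C39	8071	Ogataea (Williopsis) salicorniae	9	1	1	1	0	0	0	1	0	1	1	0	1	1	1
D	C20	4111	Ambrosiozyma platypodis	13	0	1	1	1	1	1	1	1	1	1	1	1	1	1
E	C21	4140	Nakazawaea (Pichia) holstii	14	1	1	1	1	1	1	1	1	1	1	1	1	1	1
E	C15	2286	Peterozyma (Pichia) xylosa	12	1	1	1	0	1	1	1	1	1	1	1	0	1	1
F	C18	2555	Saccharomycopsis javanensis	10	0	0	1	1	1	1	0	1	1	1	0	1	1	1
G	C34	6986	Wickerhamomyces (Pichia) alni	13	1	1	1	0	1	1	1	1	1	1	1	1	1	1
G	C36	7111	Phaffomyces (Pichia) antillensis	11	1	1	1	0	1	1	0	1	1	1	1	1	1	0
G	C23	5456	Barnettozyma (Pichia) salicaria	13	1	1	1	1	1	1	1	1	1	1	1	1	1	0
G	C33	6940	Starmera (Pichia) amethionina	11	1	1	1	1	1	1	0	1	1	1	0	1	1	0
G	C35	7023	Cyberlindnera (Lindnera, Pichia) mississippiensis	11	1	1	1	0	1	1	1	1	1	0	1	1	1	0
G	C02	254	Cyberlindnera (Lindnera, Williopsis) saturnus	11	1	1	1	0	1	1	1	1	0	1	1	1	1	0
H	C03	398	Kazachstania (Saccharomyces) unisporus	10	1	1	1	1	0	1	0	1	0	1	1	1	1	0
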