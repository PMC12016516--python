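gene_id	annotation	complex_acronym	subunit	tag_terminus
TK0135	Indolepyruvate-Fd oxidoreductase, beta subunit	IOR	beta1	C
TK0136	Indolepyruvate-Fd oxidoreductase, alpha subunit	IOR	alpha1	C
TK0650	Rubrerythrin-related protein	RBR1	RBR1	C
TK0826	Rubrerythrin Mn-catalase	RBR2	RBR2	C
TK1088	Geranylgeranyl reductase	GGR	GGR	C
TK1123	2-Oxoacid:ferredoxin oxidoreductase, gamma1 subunit	OGOR	gamma1	C
TK1129	2-Oxoacid:ferredoxin oxidoreductase, beta2 subunit	OGOR	beta2	N
TK1130	2-Oxoacid:ferredoxin oxidoreductase, alpha2 subunit	OGOR	alpha2	N
TK1215	Membrane-bound sulfane reductase, NiFe-hydrogenase large subunit 2	MBS	MBS-L	C
TK1325	Ferredoxin:NADP oxidoreductase, alpha subunit	FNOR1	alpha	C
TK1326	Ferredoxin:NADP oxidoreductase, beta subunit	FNOR1	beta	C
TK1684	Ferredoxin:NADP oxidoreductase, alpha subunit	FNOR2	alpha	C
TK1685	Ferredoxin:NADP oxidoreductase, beta subunit	FNOR2	beta	C
TK1978	2-Oxoisovalerate-ferredoxin oxidoreductase, gamma subunit	VOR/POR	gamma	C
TK1979	2-Oxoisovalerate-ferredoxin oxidoreductase, delta subunit	VOR	delta	C
TK1980	2-Oxoisovalerate-ferredoxin oxidoreductase, alpha subunit	VOR	alpha	C
TK1981	2-Oxoisovalerate-ferredoxin oxidoreductase, beta subunit	VOR	beta	C
TK1982	Pyruvate:ferredoxin oxidoreductase, delta subunit	POR	delta	C
TK1983	Pyruvate:ferredoxin oxidoreductase, alpha subunit	POR	alpha	C
TK1984	Pyruvate:ferredoxin oxidoreductase, beta subunit	POR	beta	C
TK2075	[4Fe-4S] cluster-binding protein associated with FDH	FDH	gamma2	C
TK2076	Formate dehydrogenase, alpha subunit	FDH	alpha	C
TK2077	Formate dehydrogenase, [4Fe-4S] cluster-binding protein	FDH	gamma3	C
TK2078	[4Fe-4S] cluster-binding protein associated with FDH	FDH	gamma4	C
TK2163	Glyceraldehyde-3-phosphate:ferredoxin oxidoreductase	GAPOR	GAPOR	C
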