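orf	fragment	gene	length_aa	ornv_homolog	core	split
DuhNV_F1_ORF1	F1	ND	240	OrNV_gp129/gp136	0	0
DuhNV_F1_ORF2	F1	tk/GrBNV_gp17-like	648	OrNV_gp137	0	0
DuhNV_F1_ORF3	F1	ND	149	OrNV_orfC20	0	0
DuhNV_F1_ORF4	F1	ND	594	OrNV_gp138	0	0
DuhNV_F1_ORF5	F1	dnapol	695	OrNV_gp001	1	1
DuhNV_F2_ORF1	F2	dnapol	633	OrNV_gp001	1	1
DuhNV_F2_ORF2	F2	trypsin-like serine protease-like protein	339	OrNV_gp002	0	0
DuhNV_F2_ORF3	F2	trypsin-like serine protease-like protein	427	OrNV_gp002	0	0
DuhNV_F2_ORF4	F2	ND	395	OrNV_gp003	0	0
DuhNV_F2_ORF5	F2	Ac81	173	OrNV_gp004	1	0
DuhNV_F2_ORF6	F2	thymidylate synthase/pyrimidine hydroxymethylase-like	296	OrNV_gp006	0	0
DuhNV_F2_ORF7	F2	ND	143	OrNV_gp098	0	0
DuhNV_F2_ORF8	F2	mRNA decapping enzyme 2-like	245	OrNV_gp097	0	0
DuhNV_F2_ORF9	F2	lef-9	505	OrNV_gp096	1	0
DuhNV_F2_ORF10	F2	ND	314	OrNV_gp095	0	0
DuhNV_F2_ORF11	F2	ND	162	OrNV_gp094	0	0
DuhNV_F2_ORF12	F2	cl17238, RING-Ubox	329	no hit	0	0
DuhNV_F2_ORF13	F2	None	62	no hit	0	0
DuhNV_F2_ORF14	F2	None	63	no hit	0	0
DuhNV_F2_ORF15	F2	cl25745, pfam05764	1412	OrNV_gp090	0	0
DuhNV_F2_ORF16	F2	None	148	no hit	0	0
DuhNV_F2_ORF17	F2	None	78	no hit	0	0
DuhNV_F2_ORF18	F2	38k	276	OrNV_gp087	1	0
DuhNV_F2_ORF19	F2	ND	189	OrNV_gp086	0	0
DuhNV_F2_ORF20	F2	ND	227	OrNV_gp080	0	0
DuhNV_F2_ORF21	F2	ND	89	OrNV_gp079	0	0
DuhNV_F2_ORF22	F2	ND	52	OrNV_gp076	0	0
DuhNV_F2_ORF23	F2	dnaint/rec	389	OrNV_gp075	0	0
DuhNV_F2_ORF24	F2	None	61	no hit	0	0
DuhNV_F2_ORF25	F2	ND	593	OrNV_gp073	0	0
DuhNV_F2_ORF26	F2	Ac68	136	OrNV_gp072	1	0
DuhNV_F2_ORF27	F2	None	56	no hit	0	0
DuhNV_F2_ORF28	F2	lef-8	988	OrNV_gp064	1	0
DuhNV_F2_ORF29	F2	ND	74	OrNV_gp063	0	0
DuhNV_F2_ORF30	F2	ND	88	OrNV_gp062	0	0
DuhNV_F2_ORF31	F2	ND	140	OrNV_gp061	0	0
DuhNV_F2_ORF32	F2	pif-1	489	OrNV_gp060	1	0
DuhNV_F2_ORF33	F2	lef-3	177	OrNV_gp059	1	0
DuhNV_F2_ORF34	F2	HZV_115-like protein	425	OrNV_gp058	0	0
DuhNV_F2_ORF35	F2	patatin-like phospholipase-like protein	397	OrNV_gp057	0	0
DuhNV_F2_ORF36	F2	ND	576	OrNV_gp056	0	0
DuhNV_F2_ORF37	F2	ND	458	OrNV_gp054	0	0
DuhNV_F2_ORF38	F2	ND	234	OrNV_gp053	0	0
DuhNV_F2_ORF39	F2	lef-5	82	OrNV_gp052	1	0
DuhNV_F2_ORF40	F2	rr1	1045	OrNV_gp051	0	0
DuhNV_F3_ORF1	F3	mitochondrial carrier protein-like protein	293	OrNV_gp011	0	0
DuhNV_F3_ORF2	F3	ND	231	OrNV_gp013	0	0
DuhNV_F3_ORF3	F3	None	76	no hit	0	0
DuhNV_F3_ORF4	F3	vp39	250	OrNV_gp015	1	0
DuhNV_F3_ORF5	F3	polh/gran	404	OrNV_gp016	0	0
DuhNV_F3_ORF6	F3	pif-2	376	OrNV_gp017	1	0
DuhNV_F3_ORF7	F3	None	388	no hit	0	0
DuhNV_F3_ORF8	F3	ND	131	OrNV_orfC1	0	0
DuhNV_F3_ORF9	F3	ND	509	OrNV_gp018	0	0
DuhNV_F3_ORF10	F3	Ac46	89	OrNV_gp019	0	0
DuhNV_F3_ORF11	F3	p47	324	OrNV_gp020	1	0
DuhNV_F3_ORF12	F3	EXL15_gp12_like/DUF4679	432	no hit	0	0
DuhNV_F3_ORF13	F3	ND	241	OrNV_gp022	0	0
DuhNV_F3_ORF14	F3	guanylate kinase-like protein	245	OrNV_gp023	0	0
DuhNV_F3_ORF15	F3	ND	196	OrNV_gp024	0	0
DuhNV_F3_ORF16	F3	ND	550	OrNV_gp025	0	0
DuhNV_F3_ORF17	F3	B2K52_gp057/Smc	858	no hit	0	0
DuhNV_F3_ORF18	F3	ND	422	OrNV_gp027	0	0
DuhNV_F3_ORF19	F3	PPK13561/EAL domain	297	OrNV_gp028	0	0
DuhNV_F3_ORF20	F3	ND	232	OrNV_gp029	0	0
DuhNV_F3_ORF21	F3	vlf-1	504	OrNV_gp030	1	0
DuhNV_F3_ORF22	F3	19k/pif-5	281	OrNV_gp033	1	0
DuhNV_F3_ORF23	F3	dnahel	1390	OrNV_gp034	1	0
DuhNV_F3_ORF24	F3	None	96	no hit	0	0
DuhNV_F3_ORF25	F3	None	157	no hit	0	0
DuhNV_F3_ORF26	F3	61k AcORF9	575	OrNV_gp037	0	0
DuhNV_F3_ORF27	F3	ND	199	OrNV_gp039	0	0
DuhNV_F3_ORF28	F3	ND	166	OrNV_gp040	0	0
DuhNV_F3_ORF29	F3	ND	110	OrNV_gp041	0	0
DuhNV_F3_ORF30	F3	lef-4	417	OrNV_gp042	1	0
DuhNV_F3_ORF31	F3	tk/GrBNV-gp74_like	197	OrNV_gp044	0	0
DuhNV_F3_ORF32	F3	ND	403	OrNV_gp045	0	0
DuhNV_F3_ORF33	F3	ND	591	OrNV_gp046	0	0
DuhNV_F3_ORF34	F3	ND	293	OrNV_gp047	0	0
DuhNV_F3_ORF35	F3	energy-coupling factor ABC transporter	490	no hit	0	0
DuhNV_F3_ORF36	F3	None	66	no hit	0	0
DuhNV_F3_ORF37	F3	None	278	no hit	0	0
DuhNV_F3_ORF38	F3	ND	592	OrNV_gp132	0	0
DuhNV_F3_ORF39	F3	None	868	no hit	0	0
DuhNV_F3_ORF40	F3	None	85	no hit	0	0
DuhNV_F4_ORF1	F4	None	76	no hit	0	0
DuhNV_F4_ORF2	F4	rr2	358	OrNV_gp102	0	0
DuhNV_F4_ORF3	F4	None	616	no hit	0	0
DuhNV_F4_ORF4	F4	ND	91	OrNV_gp104	0	0
DuhNV_F4_ORF5	F4	ND	408	OrNV_gp105	0	0
DuhNV_F4_ORF6	F4	vp91	695	OrNV_gp106	1	0
DuhNV_F4_ORF7	F4	iap-3	202	OrNV_gp134	1	0
DuhNV_F4_ORF8	F4	None	68	no hit	0	0
DuhNV_F4_ORF9	F4	pif-3	202	OrNV_gp107	1	0
DuhNV_F4_ORF10	F4	dnahel2	839	OrNV_gp108	0	0
DuhNV_F4_ORF11	F4	None	120	no hit	0	0
DuhNV_F4_ORF12	F4	Ac92	410	OrNV_gp113	1	0
DuhNV_F4_ORF13	F4	ND	566	OrNV_gp114	0	0
DuhNV_F4_ORF14	F4	odv-e56	420	OrNV_gp115	1	0
DuhNV_F4_ORF15	F4	ND	345	OrNV_gp116	0	0
DuhNV_F4_ORF16	F4	tk (guanosine monophosphate kinase)	321	OrNV_gp117	0	0
DuhNV_F4_ORF17	F4	ND	266	OrNV_gp118	0	0
DuhNV_F4_ORF18	F4	ND	454	OrNV_gp119	0	0
DuhNV_F4_ORF19	F4	ND	1285	OrNV_gp120	0	0
DuhNV_F4_ORF20	F4	dnalig	423	OrNV_gp121	0	0
DuhNV_F4_ORF21	F4	ND	143	OrNV_gp122	0	0
DuhNV_F4_ORF22	F4	ND	124	OrNV_gp123	0	0
DuhNV_F4_ORF23	F4	ND	476	OrNV_gp124	0	1
DuhNV_F5_ORF1	F5	tk/GrBNV_gp044_like	352	OrNV_gp125	0	0
DuhNV_F5_ORF2	F5	p74	712	OrNV_gp126	1	0
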