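# Functional-group occurrence catalog (154 SMARTS entries).
# Openly authored set of common organic functional groups; user-replaceable.
# columns: index<TAB>SMARTS<TAB>name
1	[CX4H3][#6]	methyl on carbon
2	[CX4H2]([#6])[#6]	secondary sp3 carbon (CH2)
3	[CX4H1]([#6])([#6])[#6]	tertiary sp3 carbon (CH)
4	[CX4H0]([#6])([#6])([#6])[#6]	quaternary sp3 carbon
5	[CX3H2]=[CX3]	terminal alkene =CH2
6	[CX3H1]=[CX3]	alkene =CH-
7	[CX3H0](=[CX3])([#6])[#6]	trisubstituted alkene carbon
8	[CX3]=[CX3]	C=C double bond
9	[CX3](=[CX3])[CX3]=[CX3]	conjugated diene
10	[CX2]#[CX2]	C#C triple bond
11	[CX2H1]#[CX2]	terminal alkyne CH
12	[CX4H3]	any methyl group
13	C=C=C	allene
14	c	aromatic carbon
15	[cH]	unsubstituted aromatic CH
16	[cH0]	substituted aromatic carbon
17	c1ccccc1	benzene ring
18	c[CX4]	benzylic sp3 carbon
19	c[CX4H3]	aromatic methyl (toluene-like)
20	c[CX3]=[CX3]	styrene-like vinyl on ring
21	c1ccc2ccccc2c1	fused bicyclic aromatic (naphthalene)
22	cC=O	aryl carbonyl
23	[OX2H]	hydroxyl (any)
24	[CX4H2][OX2H]	primary alcohol
25	[CX4H1]([#6])[OX2H]	secondary alcohol
26	[CX4H0]([#6])([#6])[OX2H]	tertiary alcohol
27	[c][OX2H]	phenol
28	[OX2H][CX4][CX4][OX2H]	1,2-diol
29	[OX2H0]([#6])[#6]	ether oxygen
30	[CX4][OX2H0][CX4]	dialkyl ether
31	[c][OX2H0][CX4]	alkyl aryl ether
32	[c][OX2H0][c]	diaryl ether
33	[c][OX2H0][CX4H3]	aromatic methoxy
34	[CX4]1[OX2][CX4]1	epoxide
35	[CX4]([OX2][#6])[OX2][#6]	acetal/ketal carbon
36	[CX4]([OX2H])[OX2][#6]	hemiacetal carbon
37	[OX2]([CX4])[OX2]	peroxide-type O-O
38	[CX3]=[OX1]	carbonyl group
39	[CX3H1](=O)[#6]	aldehyde
40	[CX3H1](=O)[c]	aromatic aldehyde
41	[#6][CX3](=O)[#6]	ketone
42	[CX4][CX3](=O)[CX4]	dialkyl ketone
43	[c][CX3](=O)[#6]	aryl ketone
44	[CX3](=O)[OX2H]	carboxylic acid
45	[c][CX3](=O)[OX2H]	aromatic carboxylic acid
46	[CX3](=O)[O-]	carboxylate anion
47	[CX3](=O)[OX2H0][#6]	ester
48	[CX3](=O)[OX2H0][CX4]	alkyl ester
49	[c][CX3](=O)[OX2H0]	aroyl ester (benzoate-like)
50	[C;R](=O)[O;R]	lactone
51	[CX3](=O)[OX2][CX3](=O)	acid anhydride
52	[OX2][CX3](=O)[OX2]	carbonate
53	[CX3](=O)[F,Cl,Br,I]	acyl halide
54	[CX3](=O)[CX3](=O)	1,2-dicarbonyl
55	[CX3](=O)[CX4][CX3](=O)	1,3-dicarbonyl
56	[OX2H][CX3]=[CX3]	enol
57	[NX3H2][CX4]	primary aliphatic amine
58	[NX3H1]([CX4])[CX4]	secondary aliphatic amine
59	[NX3H0]([CX4])([CX4])[CX4]	tertiary aliphatic amine
60	[NX3H2][c]	primary aromatic amine (aniline)
61	[NX3H1]([c])[#6]	secondary aromatic amine
62	[NX3H0]([c])([#6])[#6]	tertiary aromatic amine
63	[NX4+]	quaternary/protonated ammonium
64	[NX3][NX3]	hydrazine N-N
65	[NX2]=[NX2]	azo group
66	[NX2]=[CX3]	imine C=N
67	[NX2]([OX2H])=[CX3]	oxime
68	[NX1]#[CX2]	nitrile
69	[c][CX2]#[NX1]	aromatic nitrile
70	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	nitro group
71	[c][$([NX3](=O)=O),$([NX3+](=O)[O-])]	aromatic nitro
72	[NX2]=[OX1]	nitroso
73	[NX3][OX2H]	hydroxylamine
74	[NX1]=[NX2+]=[NX1-]	azide
75	[NX3][CX3]=[OX1]	amide N-C=O
76	[NX3H2][CX3]=[OX1]	primary amide
77	[NX3H1]([#6])[CX3]=[OX1]	secondary amide
78	[NX3H0]([#6])([#6])[CX3]=[OX1]	tertiary amide
79	[N;R][C;R]=O	lactam
80	[NX3][CX3](=[OX1])[NX3]	urea
81	[NX3][CX3](=[OX1])[OX2]	carbamate
82	[NX3][CX3](=[NX2])[NX3]	guanidine
83	[NX2]=[CX2]=[OX1]	isocyanate
84	[NX2]=[CX2]=[SX1]	isothiocyanate
85	[SX2][CX2]#[NX1]	thiocyanate
86	n	aromatic nitrogen
87	[nH]	pyrrole-type NH
88	[nX2H0]	pyridine-type nitrogen
89	o	aromatic oxygen (furan)
90	s	aromatic sulfur (thiophene)
91	c1ccncc1	pyridine ring
92	c1cc[nH]c1	pyrrole ring
93	c1ccoc1	furan ring
94	c1ccsc1	thiophene ring
95	c1cncnc1	pyrimidine ring
96	[n;R1][c;R1][n;R1]	imidazole-like N-C-N
97	[SX2H]	thiol
98	[SX2]([#6])[#6]	sulfide (thioether)
99	[SX2]([CX4])[CX4]	dialkyl sulfide
100	[SX2][SX2]	disulfide
101	[SX3](=[OX1])([#6])[#6]	sulfoxide
102	[SX4](=[OX1])(=[OX1])([#6])[#6]	sulfone
103	[SX4](=[OX1])(=[OX1])[OX2H]	sulfonic acid
104	[SX4](=[OX1])(=[OX1])[OX2][#6]	sulfonate ester
105	[SX4](=[OX1])(=[OX1])[NX3]	sulfonamide
106	[CX3]=[SX1]	thiocarbonyl
107	[NX3][CX3](=[SX1])[NX3]	thiourea
108	[c][SX2]	aryl sulfur
109	[PX3]	trivalent phosphorus (phosphine)
110	[PX4](=[OX1])	pentavalent P=O
111	[PX4](=[OX1])([OX2])([OX2])[OX2]	phosphate triester/acid
112	[PX4](=[OX1])([#6])([OX2])[OX2]	phosphonate
113	[PX4](=[SX1])	thiophosphoryl P=S
114	[F]	fluorine (any)
115	[Cl]	chlorine (any)
116	[Br]	bromine (any)
117	[I]	iodine (any)
118	[CX4][F]	aliphatic C-F
119	[CX4][Cl]	aliphatic C-Cl
120	[CX4][Br]	aliphatic C-Br
121	[CX4][I]	aliphatic C-I
122	[c][F]	aromatic C-F
123	[c][Cl]	aromatic C-Cl
124	[c][Br]	aromatic C-Br
125	[c][I]	aromatic C-I
126	[CX4]([F])([F])[F]	trifluoromethyl
127	[CX4]([Cl])([Cl])[Cl]	trichloromethyl
128	[CX4]([Cl])[Cl]	geminal dichloride
129	[CX3](=[CX3])[Cl]	vinyl chloride
130	[BX3]	trivalent boron
131	[BX3]([OX2H])[OX2H]	boronic acid
132	[BX4-]	borate anion
133	[Si]	silicon (any)
134	[SiX4]([#6])([#6])[#6]	trialkylsilyl
135	[C;R]1[C;R][C;R]1	cyclopropane ring
136	[C;R]1[C;R][C;R][C;R]1	cyclobutane ring
137	[C;R]1[C;R][C;R][C;R][C;R]1	cyclopentane ring
138	[C;R]1[C;R][C;R][C;R][C;R][C;R]1	cyclohexane ring
139	[C;R]=[C;R]	endocyclic C=C
140	[O;R]	ring oxygen (any saturated)
141	[N;R;!n]	ring nitrogen (non-aromatic)
142	[S;R;!s]	ring sulfur (non-aromatic)
143	[C;R][N;R][C;R]	cyclic amine fragment
144	[C;R][O;R][C;R]	cyclic ether fragment
145	[OX2H][#6][#6][NX3]	beta-amino alcohol
146	[NX3][CX4][CX3](=O)[OX2H]	alpha-amino acid motif
147	[OX2H][CX4][CX3](=O)[OX2H]	alpha-hydroxy acid motif
148	[c][OX2H0][CX3]=[OX1]	aryl ester oxygen
149	[CX4]([OX2H])[CX2]#[CX2]	propargylic alcohol
150	[CX3](=O)[NX3][c]	anilide
151	[c][NX2]=[NX2][c]	aromatic azo (azobenzene-like)
152	[CX4]([#6])([#6])([#6])[OX2H0]	tert-alkyl ether carbon
153	[#6][OX2][CX4H2][OX2][#6]	methylenedioxy-like O-CH2-O
154	[F,Cl,Br,I][c]1[c][c][c][c][c]1[F,Cl,Br,I]	ortho-dihalobenzene
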