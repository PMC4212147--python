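# E-state fragment key: 79 Kier-Hall style valence-state atom types.
# columns: index<TAB>SMARTS<TAB>name
1	[LiD1]	sLi
2	[BeD4-2]	ssssBem
3	[BeD2]	ssBe
4	[BeD4]	ssssBe
5	[BX3H1]	ssBH
6	[BX3H0]	sssB
7	[BX4]	ssssB
8	[CX4H3]	sCH3
9	[CX3H2]=*	dCH2
10	[CX4H2]	ssCH2
11	[CX2H1]#*	tCH
12	[CX3H1](=*)*	dsCH
13	[cX3H1]	aaCH
14	[CX4H1]	sssCH
15	[CX2H0](=*)=*	ddC
16	[CX2H0](#*)*	tsC
17	[CX3H0](=*)(*)*	dssC
18	[cX3H0](:*)(:*)-*	aasC
19	[cX3H0](:*)(:*):*	aaaC
20	[CX4H0]	ssssC
21	[NX4H3+]	sNH3
22	[NX3H2]	sNH2
23	[NX4H2+]	ssNH2
24	[NX2H1]=*	dNH
25	[NX3H1]	ssNH
26	[nX3H1]	aaNH
27	[NX1H0]#*	tN
28	[NX4H1+]	sssNH
29	[NX2H0](=*)*	dsN
30	[nX2H0]	aaN
31	[NX3H0]	sssN
32	[NX3H0](=*)(=*)*	ddsN
33	[nX3H0]	aasN
34	[NX4H0+]	ssssN
35	[OX2H1]	sOH
36	[OX1H0]=*	dO
37	[OX2H0]	ssO
38	[oX2]	aaO
39	[FX1]	sF
40	[SiX4H3]	sSiH3
41	[SiX4H2]	ssSiH2
42	[SiX4H1]	sssSiH
43	[SiX4H0]	ssssSi
44	[PX3H2]	sPH2
45	[PX3H1]	ssPH
46	[PX3H0]	sssP
47	[PX4H0]=*	dsssP
48	[PX5H0]	sssssP
49	[SX2H1]	sSH
50	[SX1H0]=*	dS
51	[SX2H0]	ssS
52	[sX2]	aaS
53	[SX3H0]=*	dssS
54	[SX4H0](=*)=*	ddssS
55	[ClX1]	sCl
56	[GeX4H3]	sGeH3
57	[GeX4H2]	ssGeH2
58	[GeX4H1]	sssGeH
59	[GeX4H0]	ssssGe
60	[AsX3H2]	sAsH2
61	[AsX3H1]	ssAsH
62	[AsX3H0]	sssAs
63	[AsX4H0]=*	sssdAs
64	[AsX5H0]	sssssAs
65	[SeX2H1]	sSeH
66	[SeX1H0]=*	dSe
67	[SeX2H0]	ssSe
68	[seX2]	aaSe
69	[SeX4H0](=*)=*	ddssSe
70	[BrX1]	sBr
71	[SnX4H3]	sSnH3
72	[SnX4H2]	ssSnH2
73	[SnX4H1]	sssSnH
74	[SnX4H0]	ssssSn
75	[IX1]	sI
76	[PbX4H3]	sPbH3
77	[PbX4H2]	ssPbH2
78	[PbX4H1]	sssPbH
79	[PbX4H0]	ssssPb
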