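# Kier-Hall electrotopological-state atom types (hydrogen-suppressed graph).
# Columns: bit index, type name, element, counts of aromatic/triple/double/
# single bonds to heavy neighbours, total attached hydrogens (-1 = any).
# Special matching rules for ddsN (nitro-like N) and ddssS (sulfone-like S),
# whose published definitions use bond-order-agnostic terminal oxygens, live
# in dtikit.drug_features.
index	name	element	aromatic	triple	double	single	hydrogens
0	sLi	Li	0	0	0	1	-1
1	ssBe	Be	0	0	0	2	-1
2	ssssBe	Be	0	0	0	4	-1
3	ssBH	B	0	0	0	2	1
4	sssB	B	0	0	0	3	-1
5	ssssB	B	0	0	0	4	-1
6	sCH3	C	0	0	0	1	3
7	dCH2	C	0	0	1	0	2
8	ssCH2	C	0	0	0	2	2
9	tCH	C	0	1	0	0	1
10	dsCH	C	0	0	1	1	1
11	aaCH	C	2	0	0	0	1
12	sssCH	C	0	0	0	3	1
13	ddC	C	0	0	2	0	0
14	tsC	C	0	1	0	1	0
15	dssC	C	0	0	1	2	0
16	aasC	C	2	0	0	1	0
17	aaaC	C	3	0	0	0	0
18	ssssC	C	0	0	0	4	0
19	sNH3	N	0	0	0	1	3
20	sNH2	N	0	0	0	1	2
21	ssNH2	N	0	0	0	2	2
22	dNH	N	0	0	1	0	1
23	ssNH	N	0	0	0	2	1
24	aaNH	N	2	0	0	0	1
25	tN	N	0	1	0	0	0
26	sssNH	N	0	0	0	3	1
27	dsN	N	0	0	1	1	0
28	aaN	N	2	0	0	0	0
29	sssN	N	0	0	0	3	0
30	ddsN	N	0	0	2	1	0
31	aasN	N	2	0	0	1	0
32	ssssN	N	0	0	0	4	0
33	sOH	O	0	0	0	1	1
34	dO	O	0	0	1	0	0
35	ssO	O	0	0	0	2	0
36	aaO	O	2	0	0	0	0
37	sF	F	0	0	0	1	-1
38	sSiH3	Si	0	0	0	1	3
39	ssSiH2	Si	0	0	0	2	2
40	sssSiH	Si	0	0	0	3	1
41	ssssSi	Si	0	0	0	4	0
42	sPH2	P	0	0	0	1	2
43	ssPH	P	0	0	0	2	1
44	sssP	P	0	0	0	3	0
45	dsssP	P	0	0	1	3	0
46	sssssP	P	0	0	0	5	0
47	sSH	S	0	0	0	1	1
48	dS	S	0	0	1	0	0
49	ssS	S	0	0	0	2	0
50	aaS	S	2	0	0	0	0
51	dssS	S	0	0	1	2	0
52	ddssS	S	0	0	2	2	0
53	sCl	Cl	0	0	0	1	-1
54	sGeH3	Ge	0	0	0	1	3
55	ssGeH2	Ge	0	0	0	2	2
56	sssGeH	Ge	0	0	0	3	1
57	ssssGe	Ge	0	0	0	4	0
58	sAsH2	As	0	0	0	1	2
59	ssAsH	As	0	0	0	2	1
60	sssAs	As	0	0	0	3	0
61	sssdAs	As	0	0	1	3	0
62	sssssAs	As	0	0	0	5	0
63	sSeH	Se	0	0	0	1	1
64	dSe	Se	0	0	1	0	0
65	ssSe	Se	0	0	0	2	0
66	aaSe	Se	2	0	0	0	0
67	dssSe	Se	0	0	1	2	0
68	ddssSe	Se	0	0	2	2	0
69	sBr	Br	0	0	0	1	-1
70	sSnH3	Sn	0	0	0	1	3
71	ssSnH2	Sn	0	0	0	2	2
72	sssSnH	Sn	0	0	0	3	1
73	ssssSn	Sn	0	0	0	4	0
74	sI	I	0	0	0	1	-1
75	sPbH3	Pb	0	0	0	1	3
76	ssPbH2	Pb	0	0	0	2	2
77	sssPbH	Pb	0	0	0	3	1
78	ssssPb	Pb	0	0	0	4	0
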