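patient_id	phenotype	v1_cdna	v1_protein	v1_novel	v2_cdna	v2_protein	v2_novel	v3_cdna	v3_protein	v3_novel	phase
1	TD	c.490T>C	p.(Trp164Arg)	no							
2	MC_isolated	c.1679T>C	p.(Met560Thr)	no							
3	MC_isolated	c.2680C>T	p.(Arg894*)	no							
4	MC_isolated	c.2680C>T	p.(Arg894*)	no							
5	MC_isolated	c.2680C>T	p.(Arg894*)	no							
6	MC_isolated	c.2680C>T	p.(Arg894*)	no							
7	BD	c.32delG	p.(Gly11Valfs*66)	yes	c.2680C>T	p.(Arg894*)	no				1|2
8	BD	c.86A>C	p.(His29Pro)	no	c.771T>A	p.(Tyr257*)	yes	c.1697C>T	p.(Ala566Val)	no	1|1|2
9	BD	c.180+3A>T	splicing effect	no	c.220C>T	p.(Gln74*)	no				1|2
10	BD	c.220C>T	p.(Gln74*)	no	c.587delC	p.(Thr196Leufs*8)	yes				1|2
11	BD	c.220C>T	p.(Gln74*)	no	c.1238T>G	p.(Phe413Cys)	no				1|2
12	BD	c.313C>T	p.(Arg105Cys)	no	c.501C>G	p.(Phe167Leu)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no	
13	BD	c.433+3A>G	splicing effect	yes	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
14	BD	c.568_569delinsTC	p.(Gly190Ser)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
15	BD	c.568G>A	p.(Gly190Arg)	no	c.2680C>T	p.(Arg894*)	no				1|2
16	BD	c.568G>A	p.(Gly190Arg)	no	c.2680C>T	p.(Arg894*)	no				1|2
17	BD	c.803C>T	p.(Thr268Met)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
18	BD	c.870C>G	p.(Ile290Met)	no	c.2680C>T	p.(Arg894*)	no				1|2
19	BD	c.871G>C	p.(Glu291Gln)	yes	c.1478C>T	p.(Ala493Val)	yes				1|2
20	BD	c.905A>G	p.(Tyr302Cys)	yes	c.1295C>G	p.(Thr432Arg)	yes	c.1437_1450del	p.(Pro480Hisfs*24)	no	1|1|2
21	BD	c.905A>G	p.(Tyr302Cys)	yes	c.1295C>G	p.(Thr432Arg)	yes	c.2680C>T	p.(Arg894*)	no	1|1|2
22	BD	c.908G>A	p.(Trp303*)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
23	BD	c.1044_1156del	p.(Ala350Serfs*65)	yes	c.2284+5C>T	splicing effect	no				1|2
24	BD	c.1238T>G	p.(Phe413Cys)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
25	BD	c.1238T>G	p.(Phe413Cys)	no	c.2680C>T	p.(Arg894*)	no				1|2
26	BD	c.1238T>G	p.(Phe413Cys)	no	c.2680C>T	p.(Arg894*)	no				1|2
27	BD	c.1238T>G	p.(Phe413Cys)	no	c.2680C>T	p.(Arg894*)	no				1|2
28	BD	c.1238T>G	p.(Phe413Cys)	no	c.2680C>T	p.(Arg894*)	no				1|2
29	BD	c.1324_1325delAG	p.(Ser442Profs*66)	yes	c.1324_1325delAG	p.(Ser442Profs*66)	yes				1|2
30	BD	c.1363A>T	p.(Asn455Tyr)	yes	c.1401+3A>T	splicing effect	yes	c.2680C>T	p.(Arg894*)	no	
31	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
32	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
33	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.1437_1450del	p.(Pro480Hisfs*24)	no				1|2
34	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.1453A>G	p.(Met485Val)	no				1|2
35	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.2680C>T	p.(Arg894*)	no				1|2
36	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.2680C>T	p.(Arg894*)	no				1|2
37	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.2680C>T	p.(Arg894*)	no				1|2
38	BD	c.1437_1450del	p.(Pro480Hisfs*24)	no	c.2680C>T	p.(Arg894*)	no				1|2
39	BD	c.1445G>A	p.(Gly482Glu)	yes	c.2508+2T>A	splicing effect	yes				1|2
40	BD	c.1471+1G>A	splicing effect	no	c.2680C>T	p.(Arg894*)	no				1|2
41	BD	c.1471+1G>A	splicing effect	no	c.2680C>T	p.(Arg894*)	no				1|2
42	BD	c.1478C>A	p.(Ala493Glu)	no	c.2364+2T>A	splicing effect	no				1|2
43	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
44	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
45	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
46	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
47	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
48	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
49	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
50	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
51	BD	c.2680C>T	p.(Arg894*)	no	c.2680C>T	p.(Arg894*)	no				1|2
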