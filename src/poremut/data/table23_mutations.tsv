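label	wt	position	mut	section	effect	sec_structure	contacts	printed_rsa	printed_dv	printed_charge	printed_polarity	printed_localization	divergence
p.(Leu283Phe)	LEU	283	PHE	interface	pronounced_DN	alpha-helix H		7	23	No	No		
p.(Ile290Met)	ILE	290	MET	interface	pronounced_DN	alpha-helix H		7	-4	No	No		
p.(Glu291Lys)	GLU	291	LYS	interface	no_DN	alpha-helix H	H-bonds: Glu(OE1)-Ser541(N), Glu(OE2)-Val540(N)	9	30	Yes	No		
p.(Glu291Asp)	GLU	291	ASP	interface	pronounced_DN	alpha-helix H	H-bonds: Glu(OE1)-Ser541(N), Glu(OE2)-Val540(N)	9	-27	No	No		
p.(Phe297Ser)	PHE	297	SER	interface	pronounced_DN	beta-strand 1		9	-101	No	Yes		
p.(Tyr302His)	TYR	302	HIS	interface	pronounced_DN	alpha-helix I		9	-35	Yes	Yes		dv
p.(Trp303Arg)	TRP	303	ARG	interface	pronounced_DN	alpha-helix I	Clashes	8	-54	Yes	Yes		
p.(Phe306Leu)	PHE	306	LEU	interface	pronounced_DN	alpha-helix I		2	-23	No	No		
p.(Phe307Ser)	PHE	307	SER	interface	pronounced_DN	alpha-helix I		13	-101	No	Yes		
p.(Thr310Met)	THR	310	MET	interface	pronounced_DN	alpha-helix I		7	47	No	Yes		
p.(Ala313Thr)	ALA	313	THR	interface	pronounced_DN	alpha-helix I		4	28	No	No		
p.(Ala313Val)	ALA	313	VAL	interface	pronounced_DN	alpha-helix I		4	51	No	Yes		
p.(Arg317Gln)	ARG	317	GLN	interface	pronounced_DN	alpha-helix I		59					
p.(Gln552Arg)	GLN	552	ARG	interface	pronounced_DN	turn		40					
p.(Ile553Phe)	ILE	553	PHE	interface	weak_DN	turn		0	23	No	No		
p.(His555Asn)	HIS	555	ASN	interface	pronounced_DN	turn		16					
p.(Ile556Asn)	ILE	556	ASN	interface	weak_DN	alpha-helix Q		0	-53	Yes	Yes		charge
p.(Gly230Glu)	GLY	230	GLU	pathway	weak_DN	turn		0	78	Yes	Yes		
p.(Gly233Ser)	GLY	233	SER	pathway	no_DN	alpha-helix F		0	29	No	No		
p.(Arg421Cys)	ARG	421	CYS	pathway	weak_DN	alpha-helix L	H-bond: Arg(NH2)-Phe279(O)	29					
p.(Phe428Ser)	PHE	428	SER	pathway	no_DN	alpha-helix L	Interaction of aromatic rings: Phe428-Phe351	20					
p.(Met485Val)	MET	485	VAL	pathway	no_DN	alpha-helix N		10	23	No	No		dv_sign
p.(Thr550Met)	THR	550	MET	pathway	pronounced_DN	turn		47					
p.(Glu291Gln)	GLU	291	GLN	novel		alpha-helix H	H-bonds: Glu(OE1)-Ser541(N), Glu(OE2)-Val540(N)	9	5	Yes	No	Dimer interface	
p.(Tyr302Cys)	TYR	302	CYS	novel		alpha-helix I		9	-85	No	Yes	Dimer interface	
p.(Thr432Arg)	THR	432	ARG	novel		turn						On the surface	
p.(Asn455Tyr)	ASN	455	TYR	novel		turn						On the surface	
p.(Gly482Glu)	GLY	482	GLU	novel		turn		7	78	Yes	Yes	Channel	
p.(Ala493Val)	ALA	493	VAL	novel		alpha-helix N		1	51	No	Yes	Inside, but outside the channel and dimer interface	
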