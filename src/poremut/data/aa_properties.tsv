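res_name	volume_A3	polarity_class	charge_class
GLY	60.1	polar	neutral
ALA	88.6	polar	neutral
SER	89.0	polar	neutral
CYS	108.5	nonpolar	neutral
ASP	111.1	very_polar	negative
PRO	112.7	polar	neutral
ASN	114.1	very_polar	neutral
THR	116.1	polar	neutral
GLU	138.4	very_polar	negative
VAL	140.0	nonpolar	neutral
GLN	143.8	very_polar	neutral
HIS	153.2	very_polar	positive
MET	162.9	nonpolar	neutral
ILE	166.7	nonpolar	neutral
LEU	166.7	nonpolar	neutral
LYS	168.6	very_polar	positive
ARG	173.4	very_polar	positive
PHE	189.9	nonpolar	neutral
TYR	193.6	polar	neutral
TRP	227.8	nonpolar	neutral
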