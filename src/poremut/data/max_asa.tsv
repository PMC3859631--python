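res_name	tien_theoretical	miller
ALA	129.0	113.0
ARG	274.0	241.0
ASN	195.0	158.0
ASP	193.0	151.0
CYS	167.0	140.0
GLN	225.0	189.0
GLU	223.0	183.0
GLY	104.0	85.0
HIS	224.0	194.0
ILE	197.0	182.0
LEU	201.0	180.0
LYS	236.0	211.0
MET	224.0	204.0
PHE	240.0	218.0
PRO	159.0	143.0
SER	155.0	122.0
THR	172.0	146.0
TRP	285.0	259.0
TYR	263.0	229.0
VAL	174.0	160.0
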