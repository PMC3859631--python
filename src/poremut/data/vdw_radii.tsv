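element	radius_A
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
CL	1.75
SE	1.90
BR	1.85
I	1.98
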