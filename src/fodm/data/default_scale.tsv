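res_name	h
ALA	0.7
ARG	0.0
ASN	0.111111
ASP	0.111111
CYS	0.777778
GLN	0.111111
GLU	0.111111
GLY	0.455556
HIS	0.144444
ILE	1.0
LEU	0.922222
LYS	0.066667
MET	0.711111
PHE	0.811111
PRO	0.322222
SER	0.411111
THR	0.422222
TRP	0.4
TYR	0.355556
VAL	0.966667
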