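residue	pka
A	6.01
C	5.07
D	2.77
E	3.22
F	5.48
G	5.97
H	7.59
I	6.02
K	9.74
L	5.98
M	5.74
N	5.41
P	6.48
Q	5.65
R	10.76
S	5.68
T	5.87
V	5.97
W	5.89
Y	5.66
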