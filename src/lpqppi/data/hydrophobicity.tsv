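residue	value
A	0.61
R	0.60
N	0.06
D	0.46
C	1.07
Q	0.00
E	0.47
G	0.07
H	0.61
I	2.22
L	1.53
K	1.15
M	1.18
F	2.02
P	1.95
S	0.05
T	0.05
W	2.65
Y	1.88
V	1.32
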