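residue	value
A	-0.40
R	-0.59
N	-0.92
D	-1.31
C	0.17
Q	-0.91
E	-1.22
G	-0.67
H	-0.64
I	1.25
L	1.22
K	-0.67
M	1.02
F	1.92
P	-0.49
S	-0.55
T	-0.28
W	0.50
Y	0.23
V	0.91
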