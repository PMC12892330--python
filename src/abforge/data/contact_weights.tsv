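	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
C	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
D	0.0	0.0	1.0	1.0	0.0	0.0	-1.5	0.0	-1.5	0.0	0.0	0.0	0.0	0.0	-1.5	0.0	0.0	0.0	0.0	0.0
E	0.0	0.0	1.0	1.0	0.0	0.0	-1.5	0.0	-1.5	0.0	0.0	0.0	0.0	0.0	-1.5	0.0	0.0	0.0	0.0	0.0
F	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
H	0.0	0.0	-1.5	-1.5	0.0	0.0	1.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
I	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
K	0.0	0.0	-1.5	-1.5	0.0	0.0	1.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
L	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
M	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
N	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.5	0.0	-0.5	0.0	-0.5	-0.5	0.0	0.0	0.0
P	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
Q	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.5	0.0	-0.5	0.0	-0.5	-0.5	0.0	0.0	0.0
R	0.0	0.0	-1.5	-1.5	0.0	0.0	1.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
S	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.5	0.0	-0.5	0.0	-0.5	-0.5	0.0	0.0	0.0
T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.5	0.0	-0.5	0.0	-0.5	-0.5	0.0	0.0	0.0
V	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
W	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
Y	-1.0	-1.0	0.0	0.0	-1.0	0.0	0.0	-1.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	0.0	0.0	-1.0	-1.0	-1.0
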