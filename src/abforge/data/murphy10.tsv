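letter	group
L	L
V	L
I	L
M	L
C	C
A	A
G	G
S	S
T	S
P	P
F	F
Y	F
W	F
E	E
D	E
N	E
Q	E
K	K
R	K
H	H
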