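chain_tag	position
H	2
H	27
H	28
H	29
H	30
H	47
H	48
H	49
H	67
H	69
H	71
H	73
H	78
H	93
H	94
H	103
L	2
L	4
L	35
L	36
L	46
L	47
L	48
L	49
L	64
L	66
L	68
L	69
L	71
L	98
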