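chain_tag	variant	region_id	start	end
H	default	FR1	1	25
H	default	CDR1	26	35
H	default	FR2	36	49
H	default	CDR2	50	58
H	default	FR3	59	70
H	default	DE	71	78
H	default	FR3	79	94
H	default	CDR3	95	102
H	default	FR4	103	113
H	expanded	FR1	1	23
H	expanded	CDR1	24	36
H	expanded	FR2	37	48
H	expanded	CDR2	49	59
H	expanded	FR3	60	70
H	expanded	DE	71	78
H	expanded	FR3	79	92
H	expanded	CDR3	93	103
H	expanded	FR4	104	113
L	default	FR1	1	23
L	default	CDR1	24	34
L	default	FR2	35	49
L	default	CDR2	50	56
L	default	FR3	57	65
L	default	DE	66	71
L	default	FR3	72	88
L	default	CDR3	89	97
L	default	FR4	98	109
L	expanded	FR1	1	22
L	expanded	CDR1	23	35
L	expanded	FR2	36	48
L	expanded	CDR2	49	57
L	expanded	FR3	58	65
L	expanded	DE	66	71
L	expanded	FR3	72	87
L	expanded	CDR3	88	98
L	expanded	FR4	99	109
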