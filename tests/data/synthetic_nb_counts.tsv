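150	88	46	206
81	73	43	108
79	130	61	73
195	91	113	167
182	100	35	101
49	147	72	46
146	46	82	80
121	68	59	69
56	156	101	49
214	82	66	78
108	45	41	105
58	43	109	35
57	39	74	28
133	213	130	22
60	93	43	106
64	89	66	7
78	111	86	55
76	129	93	86
44	90	73	29
63	128	67	188
94	56	122	129
72	93	84	107
120	201	41	109
108	154	64	105
64	128	78	117
132	65	52	128
131	89	102	74
63	34	92	120
169	114	171	91
38	185	112	164
135	24	48	87
156	35	79	205
130	104	81	48
59	50	90	193
87	52	105	37
76	41	120	87
71	90	113	107
144	160	41	112
76	84	77	115
121	90	108	147
37	86	143	54
132	80	111	89
127	65	55	113
89	80	78	120
81	8	196	55
74	77	90	59
89	87	173	95
53	133	130	133
16	88	74	47
68	111	78	65
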