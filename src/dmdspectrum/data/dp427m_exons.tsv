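exon	coding_length_nt
1	31
2	62
3	93
4	78
5	93
6	173
7	119
8	182
9	129
10	189
11	182
12	151
13	120
14	102
15	108
16	180
17	176
18	124
19	88
20	242
21	181
22	146
23	213
24	114
25	156
26	171
27	183
28	136
29	149
30	162
31	111
32	174
33	156
34	171
35	180
36	129
37	171
38	123
39	138
40	154
41	182
42	195
43	173
44	148
45	176
46	148
47	150
48	186
49	102
50	109
51	233
52	118
53	212
54	155
55	190
56	173
57	157
58	121
59	269
60	147
61	79
62	61
63	62
64	75
65	202
66	86
67	158
68	167
69	112
70	137
71	39
72	66
73	66
74	160
75	242
76	125
77	93
78	32
79	12
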