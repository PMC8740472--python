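cp_id	context	log2fc
1	OCU	-0.128
2	OCU	-0.400
3	OCD	0.495
4	OCU	-0.350
5	OCU	0.247
6	OCU	-0.861
7	OCU	-1.314
8	OCD	0.144
9	OCD	0.387
10	OCD	0.748
11	OCD	1.001
12	OCD	1.251
13	OCD	0.596
14	OCU	-1.034
15	OCD	0.494
16	OCU	0.069
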