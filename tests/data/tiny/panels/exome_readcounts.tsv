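chrom	pos	ref	alt	panel_sample	var_reads	depth
2	2000124	G	A	0	63	122
2	2000124	G	A	1	99	187
2	2000124	G	A	2	103	185
2	2000124	G	A	3	89	171
2	2000124	G	A	4	27	51
2	2000835	C	G	0	44	83
2	2000835	C	G	1	30	55
2	2000835	C	G	2	47	101
2	2000931	A	T	0	123	257
3	3000058	G	C	0	46	99
3	3000058	G	C	1	35	76
3	3000058	G	C	2	45	92
3	3000058	G	C	3	137	275
3	3000058	G	C	4	94	186
3	3002891	A	G	0	20	214
3	3002891	A	G	1	17	156
3	3002891	A	G	2	4	86
3	3002891	A	G	3	7	163
3	3002891	A	G	4	3	45
3	3002891	A	G	5	5	96
3	3002891	A	G	6	4	104
3	3002891	A	G	7	15	176
3	3002891	A	G	8	6	64
3	3002891	A	G	9	16	160
3	3002891	A	G	10	3	80
3	3002891	A	G	11	3	41
3	3002891	A	G	12	3	104
3	3002891	A	G	13	6	188
3	3002891	A	G	14	18	185
3	3002891	A	G	15	10	150
3	3002891	A	G	16	13	120
3	3002891	A	G	17	4	119
3	3002891	A	G	18	9	216
3	3002891	A	G	19	3	119
3	3002891	A	G	20	3	36
3	3002891	A	G	21	7	194
3	3002891	A	G	22	3	259
3	3002891	A	G	23	3	61
3	3002891	A	G	24	4	148
3	3002891	A	G	25	9	151
3	3002891	A	G	26	16	209
3	3002891	A	G	27	16	171
3	3002891	A	G	28	9	189
3	3002891	A	G	29	7	128
3	3002891	A	G	30	18	133
3	3002891	A	G	31	3	101
3	3002891	A	G	32	11	100
3	3002891	A	G	33	5	169
3	3002891	A	G	34	19	319
3	3002891	A	G	35	3	75
3	3002891	A	G	36	3	95
3	3002891	A	G	37	25	284
3	3002891	A	G	38	3	138
3	3002891	A	G	39	7	138
3	3002891	A	G	40	25	196
3	3002891	A	G	41	21	207
3	3002891	A	G	42	3	42
3	3002891	A	G	43	6	164
3	3002891	A	G	44	3	134
3	3002891	A	G	45	12	165
3	3002891	A	G	46	3	59
3	3002891	A	G	47	3	25
3	3002891	A	G	48	9	191
3	3002891	A	G	49	7	75
3	3002891	A	G	50	14	120
3	3002891	A	G	51	10	112
3	3002891	A	G	52	7	106
3	3002891	A	G	53	5	135
3	3002891	A	G	54	9	88
3	3002891	A	G	55	7	173
3	3002891	A	G	56	30	302
3	3002891	A	G	57	17	302
3	3002891	A	G	58	7	147
3	3002891	A	G	59	21	163
3	3002891	A	G	60	8	134
3	3002891	A	G	61	6	91
3	3002891	A	G	62	9	146
3	3002891	A	G	63	3	20
3	3002891	A	G	64	7	81
3	3002891	A	G	65	4	90
3	3002891	A	G	66	3	208
3	3002891	A	G	67	12	161
3	3003949	G	A	0	35	86
3	3003949	G	A	1	65	155
3	3004340	C	T	0	5	124
3	3004340	C	T	1	3	77
3	3004340	C	T	2	3	84
3	3004340	C	T	3	11	115
3	3004340	C	T	4	3	33
3	3004340	C	T	5	6	59
3	3004340	C	T	6	4	95
3	3004340	C	T	7	4	72
3	3004340	C	T	8	3	83
3	3004340	C	T	9	7	96
3	3004340	C	T	10	3	105
3	3004340	C	T	11	3	36
3	3004340	C	T	12	12	167
3	3004340	C	T	13	6	205
3	3004340	C	T	14	18	200
3	3004340	C	T	15	5	99
3	3004340	C	T	16	9	159
3	3004340	C	T	17	3	23
3	3004340	C	T	18	3	49
3	3004340	C	T	19	5	138
3	3004340	C	T	20	6	52
3	3004340	C	T	21	3	48
3	3004340	C	T	22	6	110
3	3004340	C	T	23	11	302
3	3004340	C	T	24	5	72
3	3004340	C	T	25	6	79
3	3004340	C	T	26	6	108
3	3004340	C	T	27	3	45
3	3004340	C	T	28	29	309
3	3004340	C	T	29	17	235
3	3004340	C	T	30	7	244
3	3004340	C	T	31	22	216
3	3004340	C	T	32	4	98
3	3004340	C	T	33	3	50
3	3004340	C	T	34	4	159
3	3004340	C	T	35	3	25
3	3004340	C	T	36	6	131
3	3004340	C	T	37	7	128
3	3004340	C	T	38	3	66
3	3004340	C	T	39	11	148
3	3004340	C	T	40	4	86
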