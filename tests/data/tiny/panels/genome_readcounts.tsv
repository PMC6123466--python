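chrom	pos	ref	alt	panel_sample	var_reads	depth
2	2000835	C	G	0	97	218
3	3002891	A	G	0	3	45
3	3002891	A	G	1	3	76
3	3002891	A	G	2	11	107
3	3004340	C	T	0	3	45
3	3004340	C	T	1	3	43
3	3004340	C	T	2	6	116
3	3004340	C	T	3	11	132
3	3004340	C	T	4	6	165
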