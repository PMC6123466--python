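chrom	pos	ref	alt	call_count
2	2000124	G	A	1
2	2000835	C	G	0
2	2000931	A	T	1
3	3000058	G	C	3
3	3002761	G	T	0
3	3002891	A	G	26
3	3003949	G	A	1
3	3004340	C	T	24
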