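1	999999	1003203	PIK3CA
2	1999999	2001178	TP53
3	2999999	3004535	MAP3K1
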