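sample_id	endpoint	time	event
S0000	BCSS	9.069477127227197	1
S0001	BCSS	8.586482144949983	0
S0002	BCSS	9.196161324459082	1
S0003	BCSS	6.652763322537381	1
S0004	BCSS	9.69283266739445	1
S0005	BCSS	14.998494345456045	0
S0006	BCSS	7.538206773421114	0
S0007	BCSS	5.415531407592163	1
S0008	BCSS	25.0	0
S0009	BCSS	25.0	0
S0010	BCSS	8.137121581974226	0
S0011	BCSS	8.617831938105354	1
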