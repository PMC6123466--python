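sample_id	age	grade	nodes_positive	tumor_size_category	er_status	pr_status	her2_status	her2_amplified	subtype
S0000	58.4247568584697	2	5	1	True	True	False	False	LumA
S0001	58.48413347818174	3	1	1	True	True	False	False	LumA
S0002	61.58252156745595	2	0	3	True	True	False	False	LumB
S0003	69.49265241793074	3	3	3	True	True	False	False	LumB
S0004	65.04607872241102	2	1	2	True	True	True	True	HER2E
S0005	69.93049450118141	2	2	2	True	True	False	False	LumA
S0006	48.069923597017706	3	0	1	True	True	False	False	LumB
S0007	93.77581705080372	3	1	2	True	False	False	False	LumB
S0008	51.0017162804303	3	3	3	True	False	False	False	LumB
S0009	77.89185882940279	3	1	1	True	True	False	False	LumA
S0010	69.27588136563988	1	2	3	True	False	True	True	HER2E
S0011	70.02446428824432	1	4	2	True	False	False	False	LumB
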