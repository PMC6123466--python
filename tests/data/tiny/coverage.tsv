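sample_id	frac_bases_gt20x
S0000	0.987917
S0001	0.977967
S0002	0.974605
S0003	0.894006
S0004	0.975086
S0005	0.979873
S0006	0.887994
S0007	0.969716
S0008	0.938361
S0009	0.864505
S0010	0.963835
S0011	0.936215
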