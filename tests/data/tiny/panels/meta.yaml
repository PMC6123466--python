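n_exome_panel: 912
n_genome_panel: 87
n_unmatched_normals: 151
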