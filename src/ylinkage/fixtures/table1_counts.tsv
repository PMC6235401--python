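class	moved_to_Y	not_moved_to_Y
ancestral_Y	9	2
control	0	4
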