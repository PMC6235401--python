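species	kl-2	kl-3	PPr-Y	ORY
nannoptera	M	M	M	MF
pseudoobscura	MF	MF	MF	MF
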