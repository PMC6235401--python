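species	ORY
melanogaster	M
virilis	M
acanthoptera	M
nannoptera	MF
immigrans	M
africanus	MF
bogoriensis	MF
davidi	MF
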