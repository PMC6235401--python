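species	kl-2	kl-3	kl-5	PRY	PPr-Y	ORY	WDY	Pp1-Y1	Pp1-Y2	ARY	JY-alpha
parvula	NA	NA	M	M	NA	NA	NA	NA	NA	NA	NA
kanapiae	NA	NA	M	M	NA	NA	NA	NA	NA	NA	NA
auraria	MF	MF	MF	MF	MF	MF	MF	MF	MF	MF	MF
kikkawai	M	NA	NA	NA	NA	NA	M	NA	NA	NA	NA
lini	M	NA	NA	NA	NA	NA	M	NA	NA	NA	NA
nikananu	NA	NA	M	M	NA	M	NA	NA	NA	M	NA
diplacantha	NA	NA	MF	MF	NA	MF	NA	NA	NA	MF	NA
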