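gene	class
kl-2	ancestral_Y
kl-3	ancestral_Y
kl-5	ancestral_Y
PRY	ancestral_Y
PPr-Y	ancestral_Y
ORY	ancestral_Y
WDY	ancestral_Y
Pp1-Y1	ancestral_Y
Pp1-Y2	ancestral_Y
ARY	ancestral_Y
JY-alpha	ancestral_Y
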