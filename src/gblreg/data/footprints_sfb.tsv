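# DNase-I protected regions of the sfb cluster promoters, anchored to the
# target gene's translation start (-1 = base immediately 5' of the start codon).
promoter	gene	strand	from	to
sfb2p	sfb2	top	-55	-84
sfb2p	sfb2	bottom	-55	-82
sfbRp	sfbR	top	-136	-164
sfbRp	sfbR	bottom	-128	-157
sfb7p	sfb7	top	-100	-127
sfb7p	sfb7	bottom	-83	-112
sfbR2p	sfbR2	top	-117	-144
sfbR2p	sfbR2	bottom	-108	-136
sfbAp	sfbA	top	-63	-90
sfbAp	sfbA	bottom	-63	-90
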