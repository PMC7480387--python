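# Experimentally mapped promoters of the sfb cluster: TSP position anchored to
# the translation start, the -10 and -35 hexamers, and the hexamer spacer.
promoter	gene	tsp	minus10	minus35	spacer
sfb2p	sfb2	-35	TATCAT	AGTAGT	14
sfbRp	sfbR	-59	TAGCAT	CCGCCC	19
sfb7p	sfb7	-84	TTTAAT	TCCACT	22
sfbR2p1	sfbR2	-234	CAGGGT	CTGTCC	19
sfbR2p2	sfbR2	-108	TTTGTT	CGGAGC	21
sfbAp	sfbA	-56	TATATT	TCGCCC	21
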