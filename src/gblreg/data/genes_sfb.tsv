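# Gene order and coding strand across the sequenced GBL cluster region.
gene	strand	product
sfb1	+	large SARP-family regulator
sfb2	+	StrR-family regulator (contains TTA codon)
sfbR	+	GBL receptor
sfb4	+	cytochrome P450 monooxygenase (contains TTA codon)
sfb5	+	short-chain dehydrogenase/reductase
sfb6	+	hypothetical protein
sfb7	-	small SARP-family regulator
sfbR2	+	GBL pseudo-receptor
sfbA	+	GBL synthase (AfsA-like)
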