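# Intergenic RT-PCR co-transcription calls between adjacent same-strand genes.
gene_a	gene_b	amplified
sfb1	sfb2	false
sfb2	sfbR	false
sfbR	sfb4	false
sfb4	sfb5	true
sfb5	sfb6	true
sfbR2	sfbA	true
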