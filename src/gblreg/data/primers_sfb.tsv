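# qPCR and intergenic RT-PCR primer pairs for the sfb/fil study region.
# expected_bp applies to the pair (F row carries it).
name	sequence	target	expected_bp
qsfb2-F	GACCATGCGGATTGTCGAC	sfb2	78
qsfb2-R	TAGCGGACCTCGATGGAGTC	sfb2
qsfbR-F	CGACGGTTTCTTTTGCTTCCC	sfbR	56
qsfbR-R	ACACCTCCTCACCCTGACC	sfbR
qsfb7-F	CCCACAGTTCCTCCACCAG	sfb7	141
qsfb7-R	AAGTACTCGGCGGCTTTGC	sfb7
qsfbR2-F	AGTTGTGGGCGCGTTCTG	sfbR2	65
qsfbR2-R	TACGGCCACGGAGATGACAC	sfbR2
qsfbA-F	AGGTCTTCCTCACCGGATG	sfbA	90
qsfbA-R	TGCTGGTGAAGAAGGTGTGC	sfbA
qrrnA1-F	GACGCAACGCGAAGAACC	rrnA1	137
qrrnA1-R	TGCGGGACTTAACCCAACATC	rrnA1
RT-sfb12-F	GCCGCCCACCACCTGCTG	sfb1-sfb2	436
SfbR16F	CGACGACGAGAAATGGCGGTGG	sfb2-sfbR	575
RT-sfb2R-R	GCCGCAGCGGTCAGGATCG	sfb2-sfbR
RT-sfbR4-F	GCCCGCCTCGTCGAGCAC	sfbR-sfb4	391
RT-sfbR4-R	GGTGTGTTCGGTCCCGTAGGCG	sfbR-sfb4
RT-sfb45-F	CTGGGACGCGGTGGTGGAGGAG	sfb4-sfb5	657
RT-sfb45-R	GTTGTGGTCGTGTGCGGGCTG	sfb4-sfb5
RT-sfb56-F	GCCCGACGCCAGCAGGAAGG	sfb5-sfb6	358
RT-sfb56-R	CGAGGCTGGTTTGGGTGTGGG	sfb5-sfb6
RT-sfbR2A-F	CGGGCGTATCGGTCGAGCAG	sfbR2-sfbA	488
RT-sfbR2A-R	GCGGGTGGGCTCTTGCTGGC	sfbR2-sfbA
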