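node	parent	markers
Q	-	M242
Q1a	Q	MEH2
Q1a1	Q1a	M120
Q1a2	Q1a	M25
Q1a3	Q1a	M346
Q1a3a	Q1a3	L53
Q1a3a1	Q1a3a	L54
Q1a3a1a	Q1a3a1	M3
Q1a3a1a1	Q1a3a1a	M19
Q1a3a1a2	Q1a3a1a	M194
Q1a3a1a3	Q1a3a1a	M199
Q1a3a1a4	Q1a3a1a	SA01
Q1a3a1a5	Q1a3a1a	M557
Q1a3a1a6	Q1a3a1a	PV2
Q1a3a1a7	Q1a3a1a	NTW01
Q1a3a1b	Q1a3a1	L191
Q1a3a1c	Q1a3a1	L330
Q1a3a1d	Q1a3a1	L401
Q1a3a1f	Q1a3a1	PV3
Q1a3a1g	Q1a3a1	PV4
Q1b	Q	M378
Q1b1	Q1b	M323
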