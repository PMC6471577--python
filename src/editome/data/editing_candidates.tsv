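chrom	pos	quality	fdr	fraction_difference	gene	strand	region	substitution
19	45394416	357.14	9.99e-5	0.122	PPP1R13L	-	Intron	A>G
2	37100515	373.16	1.06e-5	0.106	EIF2AK2	-	3UTR	A>G
2	218237842	275.35	7.53e-4	0.178	ARPC2	+	Intron	A>G
X	150767753	438.58	2.39e-4	0.047	CD99L2	-	3UTR	A>G
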