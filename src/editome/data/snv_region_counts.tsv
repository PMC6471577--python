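label	count
DOWNSTREAM	3179
EXON	2386
INTERGENIC	10
INTRON	1528
SPLICE_SITE_ACCEPTOR	1
SPLICE_SITE_REGION	54
UPSTREAM	1369
UTR_3_PRIME	1260
UTR_5_PRIME	345
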