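gene_id	base_mean	log2FC	padj	gene_symbol
XLOC_048584	7.49193	-2.805	1.05e-2	THEMIS
XLOC_032992	34.69158	-2.784	2.74e-2	PTPRN
XLOC_028055	8.40907	-2.603	6.26e-3	ADGRE4P
XLOC_050480	45.34250	-2.401	6.47e-4	AC245427.9
XLOC_031488	63.22940	-2.386	9.55e-3	FNDC4
XLOC_015723	52.46403	-2.375	1.24e-2	TRAC
XLOC_050482	62.93612	-2.313	4.71e-3	TRBC2
XLOC_034173	7.15533	-2.304	1.93e-2	SIRPG
XLOC_058872	62.88279	-2.277	5.00e-3	SLC38A5
XLOC_035229	129.54309	-2.191	1.99e-2	B3GALT5
XLOC_030101	84.31897	-2.137	1.05e-2	ZAP70
XLOC_000516	38.22445	-2.130	1.02e-2	LCK
XLOC_017361	19.31762	-2.093	3.33e-4	BCL11B
XLOC_013236	25.54894	-2.078	2.13e-2	TESPA1
XLOC_043316	143.34412	-2.072	3.12e-3	IL7R
XLOC_044222	40.17459	-2.033	1.00e-2	ITK
XLOC_047901	57.73795	-1.817	2.56e-3	LTB
XLOC_027402	22.55203	-1.804	1.24e-2	PINLYP
XLOC_039524	248.13131	1.392	4.71e-3	ASTE1
XLOC_048872	4.95620	2.326	2.13e-2	AL023775.1
XLOC_044458	371.82484	2.429	6.17e-3	BTNL9
XLOC_037183	36.60827	2.447	5.00e-3	AC087857.1
XLOC_004057	13.87959	2.524	2.36e-2	TCHHL1
XLOC_029611	4.74119	2.629	1.57e-2	NA
XLOC_053736	5.04141	2.647	4.06e-2	ADAM2
XLOC_007768	6.30889	2.937	1.34e-2	NA
XLOC_051256	14.10328	3.087	5.00e-3	PHBP5
XLOC_006484	268.76888	3.304	9.15e-4	ARMS2
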