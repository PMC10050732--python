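SNP	CHR	GENE	EA	OA	EAF	BETA	SE	P	N
rs11621961	14	SERPINA6	T	C	0.357	-0.077	0.014	3.970e-08	12597
rs12589136	14	SERPINA6	T	G	0.217	0.103	0.015	3.320e-12	12597
rs2749527	14	SERPINA1	T	C	0.489	-0.081	0.012	5.210e-11	12597
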