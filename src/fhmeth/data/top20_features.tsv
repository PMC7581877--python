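rank	probe_id	gene	chrom	pos	gene_feature	direction	relative_importance
1	cg14265823	PAX3	chr2	223163326	Exon 1	hyper	100
2	cg02558132	MYLK	chr3	123411198	Intron 19	hypo	97.97
3	cg22162835	TEAD3	chr6	35457472	Intron 1	hypo	92.2
4	cg00415024		chr20	56044352	Intergenic	hypo	87.39
5	cg26426080	PRDM16	chr1	3039210	Intron 1	hypo	84.61
6	cg07051648	NTN5/SEC1P	chr19	49177693	Intron 4 (SEC1P)	hypo	76.65
7	cg05071823	DOCK11	chrX	117628671	Intergenic	hypo	61.17
8	cg05541727	EXD3	chr9	140277740	Intron 2	hyper	54.31
9	cg24051749	MYCBP	chr1	39340282	Intron 1	hypo	53.71
10	cg11478607	GSTT1	chr22	24384400	Intergenic	hyper	51.79
11	cg10020385	MAF1	chr8	145159706	Exon 1	hyper	49.8
12	cg11136235		chr10	81077552	Intergenic	hyper	48.55
13	cg16370685	SETDB1	chr1	150899163	Intron 1	hyper	46.59
14	cg09138267	LOC728743	chr7	150102791	Intron 1	hyper	46.47
15	cg04900489		chr13	31272551	Intergenic	hypo	46.29
16	cg16685760		chrX	145701257	Intergenic	hyper	46.17
17	cg07336544	KCNMA1	chr10	79194347	Intron 1	hypo	44.54
18	cg00578917	CYYR1	chr21	27945542	Exon 1	hyper	42.69
19	cg20588438	KNTC1	chr12	123089881	Exon 51	hypo	41.65
20	cg15458017		chr17	9672274	Intergenic	hyper	41.5
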