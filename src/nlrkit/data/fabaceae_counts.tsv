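species	common_name	genome_size_mb	n_annotated_genes	n_nlr_genes	n_nlr_proteins
Glycine max	Soybean	1100	89662	1356	1725
Lupinus angustifolius	Lupin	951	35179	488	488
Medicago truncatula	Barrel clover	500	59988	1540	1756
Pisum sativum	Pea	4450	57835	530	608
Phaseolus vulgaris	Common bean	587	33910	814	877
Trifolium pratense	Red clover	420	42485	1067	1074
Vigna angularis	Adzuki bean	538	34819	587	587
Vigna radiata	Mung bean	494	23977	445	453
Vigna unguiculata	Cowpea	640	54348	1002	1470
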