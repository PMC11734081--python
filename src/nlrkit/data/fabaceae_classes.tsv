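species	L	N	CN	TN	NL	CNL	TNL
Glycine max	1101	171	146	175	44	27	53
Lupinus angustifolius	437	22	18	4	2	2	1
Medicago truncatula	863	233	220	292	39	39	67
Pisum sativum	468	51	54	10	8	7	0
Phaseolus vulgaris	476	113	138	82	13	15	15
Trifolium pratense	666	173	114	65	29	11	13
Vigna angularis	422	41	67	20	8	17	10
Vigna radiata	369	42	17	11	7	0	7
Vigna unguiculata	777	191	148	239	46	34	31
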