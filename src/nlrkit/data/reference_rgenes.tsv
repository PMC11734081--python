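gene_name	accession	asserted_class	species
Rx_like	E3WF10	CN	Solanum tuberosum
refgene002	SYN00002	CNL	Arabidopsis thaliana
refgene003	SYN00003	CNL	Arabidopsis thaliana
refgene004	SYN00004	CNL	Arabidopsis thaliana
refgene005	SYN00005	CNL	Arabidopsis thaliana
refgene006	SYN00006	CNL	Arabidopsis thaliana
refgene007	SYN00007	CNL	Arabidopsis thaliana
refgene008	SYN00008	CNL	Arabidopsis thaliana
refgene009	SYN00009	CNL	Arabidopsis thaliana
refgene010	SYN00010	CNL	Arabidopsis thaliana
refgene011	SYN00011	CNL	Arabidopsis thaliana
refgene012	SYN00012	CNL	Arabidopsis thaliana
refgene013	SYN00013	LECRK	Arabidopsis thaliana
refgene014	SYN00014	LECRK	Arabidopsis thaliana
refgene015	SYN00015	LECRK	Arabidopsis thaliana
refgene016	SYN00016	LECRK	Arabidopsis thaliana
refgene017	SYN00017	LECRK	Arabidopsis thaliana
refgene018	SYN00018	LECRK	Arabidopsis thaliana
refgene019	SYN00019	LECRK	Arabidopsis thaliana
refgene020	SYN00020	LECRK	Arabidopsis thaliana
refgene021	SYN00021	LECRK	Arabidopsis thaliana
refgene022	SYN00022	LECRK	Arabidopsis thaliana
refgene023	SYN00023	LECRK	Arabidopsis thaliana
refgene024	SYN00024	LECRK	Arabidopsis thaliana
refgene025	SYN00025	LECRK	Arabidopsis thaliana
refgene026	SYN00026	LECRK	Arabidopsis thaliana
refgene027	SYN00027	LECRK	Arabidopsis thaliana
refgene028	SYN00028	LECRK	Arabidopsis thaliana
refgene029	SYN00029	LECRK	Arabidopsis thaliana
refgene030	SYN00030	LECRK	Arabidopsis thaliana
refgene031	SYN00031	LECRK	Arabidopsis thaliana
refgene032	SYN00032	LECRK	Arabidopsis thaliana
refgene033	SYN00033	LECRK	Arabidopsis thaliana
refgene034	SYN00034	LYK	Arabidopsis thaliana
refgene035	SYN00035	LYK	Arabidopsis thaliana
refgene036	SYN00036	LYK	Arabidopsis thaliana
refgene037	SYN00037	LYK	Arabidopsis thaliana
refgene038	SYN00038	LYK	Arabidopsis thaliana
refgene039	SYN00039	LYK	Arabidopsis thaliana
refgene040	SYN00040	LYK	Arabidopsis thaliana
refgene041	SYN00041	LYK	Arabidopsis thaliana
refgene042	SYN00042	LYK	Arabidopsis thaliana
refgene043	SYN00043	LYK	Arabidopsis thaliana
refgene044	SYN00044	LYK	Arabidopsis thaliana
refgene045	SYN00045	LYK	Arabidopsis thaliana
refgene046	SYN00046	LYK	Arabidopsis thaliana
refgene047	SYN00047	LYK	Arabidopsis thaliana
refgene048	SYN00048	LYP	Arabidopsis thaliana
refgene049	SYN00049	LYP	Arabidopsis thaliana
refgene050	SYN00050	LYP	Arabidopsis thaliana
refgene051	SYN00051	LYP	Arabidopsis thaliana
refgene052	SYN00052	LYP	Arabidopsis thaliana
refgene053	SYN00053	LYP	Arabidopsis thaliana
refgene054	SYN00054	N	Arabidopsis thaliana
refgene055	SYN00055	N	Arabidopsis thaliana
refgene056	SYN00056	N	Arabidopsis thaliana
RPS6_like	Q9FKN7	NL	Arabidopsis thaliana
refgene058	SYN00058	NL	Arabidopsis thaliana
refgene059	SYN00059	NL	Arabidopsis thaliana
refgene060	SYN00060	Other	Arabidopsis thaliana
refgene061	SYN00061	Other	Arabidopsis thaliana
refgene062	SYN00062	Other	Arabidopsis thaliana
refgene063	SYN00063	Other	Arabidopsis thaliana
refgene064	SYN00064	Other	Arabidopsis thaliana
refgene065	SYN00065	Other	Arabidopsis thaliana
refgene066	SYN00066	Other	Arabidopsis thaliana
refgene067	SYN00067	Other	Arabidopsis thaliana
refgene068	SYN00068	Other	Arabidopsis thaliana
refgene069	SYN00069	Other	Arabidopsis thaliana
refgene070	SYN00070	Other	Arabidopsis thaliana
refgene071	SYN00071	Other	Arabidopsis thaliana
refgene072	SYN00072	Other	Arabidopsis thaliana
refgene073	SYN00073	RLK	Arabidopsis thaliana
refgene074	SYN00074	RLK	Arabidopsis thaliana
refgene075	SYN00075	RLK	Arabidopsis thaliana
refgene076	SYN00076	RLK	Arabidopsis thaliana
refgene077	SYN00077	RLK	Arabidopsis thaliana
refgene078	SYN00078	RLK	Arabidopsis thaliana
refgene079	SYN00079	RLK	Arabidopsis thaliana
refgene080	SYN00080	RLK	Arabidopsis thaliana
refgene081	SYN00081	RLK	Arabidopsis thaliana
refgene082	SYN00082	RLP	Arabidopsis thaliana
refgene083	SYN00083	RLP	Arabidopsis thaliana
refgene084	SYN00084	RLP	Arabidopsis thaliana
refgene085	SYN00085	RLP	Arabidopsis thaliana
refgene086	SYN00086	RLP	Arabidopsis thaliana
refgene087	SYN00087	RLP	Arabidopsis thaliana
refgene088	SYN00088	T	Arabidopsis thaliana
refgene089	SYN00089	T	Arabidopsis thaliana
refgene090	SYN00090	TNL	Arabidopsis thaliana
refgene091	SYN00091	TNL	Arabidopsis thaliana
refgene092	SYN00092	TNL	Arabidopsis thaliana
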