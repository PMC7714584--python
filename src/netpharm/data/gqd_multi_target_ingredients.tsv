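molecule_id	molecule_name	herb	ob	dl
MOL000098	Quercetin	Gancao;Huanglian	46.43	0.28
MOL000173	Wogonin	Huangqin	30.68	0.23
MOL000354	Isorhamnetin	Gancao	49.6	0.31
MOL000392	Formononetin	Gancao;Gegen	69.67	0.21
MOL000422	Kaempferol	Gancao	41.88	0.24
MOL000449	Stigmasterol	Huangqin	43.83	0.76
MOL000497	Licochalcone a	Gancao	40.79	0.29
MOL002714	Baicalein	Huangqin	33.52	0.21
MOL002928	Oroxylin a	Huangqin	41.37	0.23
MOL004815	(E)-1-(2,4-Dihydroxyphenyl)-3-(2,2-dimethylchromen-6-yl)prop-2-en-1-one	Gancao	39.62	0.35
MOL004835	Glypallichalcone	Gancao	61.6	0.19
MOL004841	Licochalcone B	Gancao	76.76	0.19
MOL012245	5,7,4'-Trihydroxy-6-methoxyflavanone	Huangqin	36.63	0.27
MOL012246	5,7,4'-Trihydroxy-8-methoxyflavanone	Huangqin	74.24	0.26
MOL012266	Rivularin	Huangqin	37.94	0.37
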