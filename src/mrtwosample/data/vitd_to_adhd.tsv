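rsid	gene	chrom	pos	role	effect_allele	other_allele	eaf	exposure_beta	exposure_or	exposure_se	exposure_p	outcome_effect_allele	outcome_other_allele	outcome_beta	outcome_or	outcome_se	outcome_p	palindromic_ambiguous	proxy_of	proxy_distance	proxy_r2	proxy_dprime
rs10741657	CYP2R1			instrument	A	G	0.40	0.031		0.0022	2.05e-46	A	G		1.0048	0.0137	0.728	False
rs10745742	AMDHD1			instrument	T	C	0.40	0.017		0.0022	1.88e-14	T	C		1.0141	0.0138	0.311	False
rs12785878	NADSYN1-DHCR7			instrument	T	G	0.75	0.036		0.0022	3.80e-62	T	G		1.0313	0.0146	0.035	False
rs17216707	CYP24A1			lead_replaced	T	C	0.77	0.026		0.0027	8.14e-23								rs209955
rs209955	CYP24A1			instrument	T	C	0.31	-0.019		0.0024	2.49e-16	T	C		1.003	0.0156	0.848	False	rs17216707	-9491	0.4115	0.7908
rs3755967	GC			instrument	T	C	0.28	-0.089		0.0023	4.74e-343	T	C		1.0235	0.015	0.122	False
rs8018720	SEC23A			instrument	C	G	0.82	-0.017		0.0029	4.72e-09	C	G		0.9958	0.0185	0.819	True
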