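rsid	gene	chrom	pos	role	effect_allele	other_allele	eaf	exposure_beta	exposure_or	exposure_se	exposure_p	outcome_effect_allele	outcome_other_allele	outcome_beta	outcome_or	outcome_se	outcome_p	palindromic_ambiguous	proxy_of	proxy_distance	proxy_r2	proxy_dprime
rs11420276		1	44184192	instrument	G	GT	0.696		1.11305	0.0149	6.452e-13
rs11591402		10	106747354	instrument	A	T	0.224		0.91174	0.0164	1.76e-08	A	T	0.0012		0.0025	0.6195	True
rs1222063		1	96602440	lead_replaced	A	G	0.328		1.10098	0.0174	3.068e-08								rs1222067
rs1222067		1	96597502	instrument	A	C	0.688		0.92635	0.0155	7.908e-07	A	C	0.0008		0.0026	0.7464	False	rs1222063	-4938	0.679350
rs1427829		2	89760744	instrument	A	G	0.434		1.08567	0.0136	1.349e-09	A	G	0.0027		0.0021	0.1974	False
rs212178		16	72578131	lead_replaced	A	G	0.883		0.88950	0.0205	1.198e-08								rs12596294
rs12596294		16	72587093	instrument	A	T	0.098		1.12008	0.0207	4.157e-08	A	T	0.0029		0.0034	0.3873	True	rs212178	8962	0.924371
rs281324		15	47754018	instrument	T	C	0.531		0.92450	0.0135	6.684e-09	T	C	0.0024		0.0021	0.2426	False
rs28411770		4	31151456	lead_replaced	T	C	0.651		1.08992	0.0151	1.152e-08								rs7674790
rs7674790		4	31149277	instrument	A	T	0.610		1.07455	0.014	2.996e-07	A	T	0.0002		0.0022	0.9348	True	rs28411770	-2179	0.797643
rs4858241		3	20669071	lead_replaced	T	G	0.622		1.08567	0.0143	8.172e-09								rs17808771
rs17808771		3	20691823	instrument	A	T	0.758		1.07326	0.0153	3.773e-06	A	T	0.0008		0.0024	0.7341	True	rs4858241	22752	0.646552
rs4916723		5	87854395	instrument	A	C	0.573		0.92515	0.0138	1.807e-08	A	C	-0.0016		0.0021	0.4515	False
rs5886709		7	114086133	instrument	G	GTC	0.463		1.07993	0.0137	2.056e-08
rs74760947		8	34352610	lead_replaced	A	G	0.957		0.83560	0.0317	1.393e-08								rs6990255
rs6990255		8	34126948	instrument	T	C	0.0586481		1.18270	0.0315	1.03e-07	T	C	-0.0058		0.0043	0.1779	False	rs74760947	-225662	0.947204
rs9677504		2	215181889	instrument	A	G	0.109		1.12019	0.0213	9.829e-08	A	G	0.0012		0.0033	0.7171	False
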