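rsid	position	effect_allele	other_allele	beta	se	pvalue
rs727428	7478517	T	C	-0.073	0.01	1.26e-12
rs1799941	7474148	A	G	0.082	0.012	1.39e-12
rs17806566	7292887	C	T	-0.168	0.03	2.61e-8
rs9913778	7474626	T	C	-0.106	0.019	3.05e-8
rs9900162	7387788	G	A	-0.07	0.013	6.13e-8
rs35894069	7335900	A	G	0.054	0.011	5.74e-7
rs9908275	7367048	T	C	-0.065	0.014	1.59e-6
rs4511593	7396260	C	T	0.051	0.011	1.73e-6
rs55784804	7477185	T	G	-0.075	0.018	2.25e-5
rs3853818	7287026	T	C	-0.044	0.01	2.36e-5
rs12944954	7425855	G	A	-0.181	0.043	2.88e-5
rs55894190	7323962	C	T	-0.042	0.01	6.90e-5
rs8069501	7335692	G	A	-0.087	0.023	1.52e-4
rs858517	7474996	C	T	-0.091	0.026	4.44e-4
rs2955611	7490299	C	A	-0.053	0.016	9.08e-4
rs12942088	7423503	C	T	-0.033	0.01	1.59e-3
rs2302762	7299585	T	C	-0.034	0.011	3.06e-3
rs12936934	7441490	T	C	-0.036	0.014	9.74e-3
rs4968211	7399786	A	G	-0.063	0.026	1.4e-2
rs4796305	7276779	G	T	-0.037	0.019	4.6e-2
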