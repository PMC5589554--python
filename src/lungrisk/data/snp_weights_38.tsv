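rsid	chrom	pos	allele_a	allele_b	effect_allele	flipped	maf	hwe_p	or	or_low	or_high	p	beta	flagged
rs17728461	chr22	30598552	C	G	C	0	0.17	0.7	1.37	1.24	1.51	8.50E-10	0.0535	0
rs465498	chr5	1325803	A	G	G	1	0.16	0.11	0.75	0.67	0.84	6.83E-07	0.0523	1
rs753955	chr13	24293859	A	G	A	0	0.29	0.76	1.23	1.13	1.35	1.33E-06	0.0482	0
rs2895680	chr5	146644115	T	C	T	0	0.28	0.62	1.21	1.11	1.32	1.04E-05	0.0415	0
rs12296850	chr12	100820085	A	G	G	1	0.25	0.14	0.82	0.75	0.9	3.09E-05	0.0402	1
rs4488809	chr3	189356261	C	T	C	0	0.47	1.0	1.21	1.12	1.31	2.39E-06	0.0375	0
rs2736100	chr5	1286516	A	C	A	0	0.41	0.3	1.2	1.11	1.3	8.84E-06	0.0374	0
rs9439519	chr1	5364634	T	C	T	0	0.27	0.93	1.18	1.08	1.29	2.18E-04	0.0361	0
rs383362	chr16	79245820	G	T	G	0	0.15	0.62	1.17	1.05	1.3	3.97E-03	0.0357	0
rs6573	chr1	112255389	C	A	A	1	0.13	0.47	0.82	0.73	0.93	1.27E-03	0.0346	1
rs247008	chr5	131447104	G	A	A	1	0.47	0.06	0.83	0.77	0.9	6.27E-06	0.0343	1
rs4809957	chr20	52771171	G	A	G	0	0.35	0.2	1.18	1.09	1.28	7.11E-05	0.0341	0
rs4246215	chr11	61564299	G	T	T	1	0.41	0.85	0.82	0.76	0.89	2.04E-06	0.0335	1
rs1663689	chr10	9025195	T	C	C	1	0.42	0.97	0.85	0.79	0.92	8.03E-05	0.0313	1
rs7086803	chr10	114498476	G	A	G	0	0.28	0.62	1.16	1.06	1.26	1.06E-03	0.0297	0
rs4083914	chr6	153427706	G	C	G	0	0.14	0.19	1.16	1.04	1.29	7.36E-03	0.0293	0
rs2286455	chr4	16020162	C	T	C	0	0.23	0.14	1.15	1.05	1.26	3.70E-03	0.0284	1
rs3764340	chr16	78466437	C	G	C	0	0.07	1.0	1.2	1.04	1.39	0.012	0.0283	0
rs36600	chr22	30337586	C	T	C	0	0.09	0.82	1.39	1.22	1.58	8.38E-07	0.0281	0
rs842461	chr3	195535614	T	G	T	0	0.27	0.27	1.18	1.09	1.29	1.19E-04	0.0253	0
rs2285053	chr16	55512377	C	T	T	1	0.24	0.25	0.9	0.82	0.99	0.029	0.0247	0
rs2131877	chr3	194858374	A	G	G	1	0.44	0.07	0.91	0.84	0.99	0.025	0.024	1
rs1801133	chr1	11856378	G	A	G	0	0.44	0.36	1.16	1.07	1.26	1.76E-04	0.0232	0
rs3866958	chr17	19281006	C	A	A	1	0.15	0.44	0.87	0.78	0.97	0.015	0.0225	1
rs1800625	chr6	32152442	A	G	A	0	0.13	0.75	1.12	1.0	1.26	0.046	0.0218	0
rs9387478	chr6	117786180	C	A	A	1	0.5	0.86	0.91	0.84	0.98	0.013	0.0216	1
rs743572	chr10	104597152	G	A	G	0	0.4	1.0	1.09	1.01	1.18	0.026	0.0209	0
rs4291	chr17	61554194	A	T	A	0	0.37	0.08	1.1	1.02	1.2	0.015	0.0208	0
rs10845498	chr12	12394574	A	G	G	1	0.18	0.11	0.89	0.8	0.98	0.023	0.0202	1
rs7326277	chr13	28876214	T	C	C	1	0.33	0.65	0.91	0.84	0.99	0.038	0.0189	1
rs931127	chr11	65405300	G	A	A	1	0.48	0.08	0.91	0.84	0.99	0.028	0.0189	1
rs2016520	chr6	35378778	T	C	T	0	0.27	0.47	1.1	1.01	1.2	0.037	0.0161	0
rs25406	chr20	5099636	G	A	A	1	0.36	0.56	0.91	0.84	0.99	0.025	0.0158	1
rs2240688	chr4	15970349	T	G	G	1	0.26	0.58	0.91	0.83	1.0	0.040	0.0134	1
rs34843907	chr6	32610059	G	T	G	0	0.33	0.39	1.09	1.0	1.18	0.041	0.0121	0
rs2070600	chr6	32151443	C	T	T	1	0.23	0.29	0.91	0.83	1.0	0.046	0.0109	1
rs189037	chr11	108093833	G	A	G	0	0.43	0.07	1.08	1.0	1.18	0.049	0.008	0
rs3817963	chr6	32368087	T	C	T	0	0.25	0.07	1.08	0.99	1.18	0.078	0.0075	0
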