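chrom	locus	rsid	effect_allele	raf_controls	raf_cases	or_local	se_local	p_local	or_pooled	p_het_fdr
1	PEX14	rs616488	G	0.348	0.361	1.06	0.09	0.510	0.94	0.790
1	PTPN22/BCL2L15/AP4B1/DCLRE1B/HIPK1	rs11552449	A	0.596	0.556	0.85	0.08	0.040	1.06	0.068
1	FCGR1B	rs11249433	G	0.029	0.026	0.85	0.25	0.517	1.09	0.371
2	INHBB	rs4849887	A	0.259	0.269	1.05	0.09	0.634	0.92	0.561
2	METAP1D/DLX1/DLX2	rs2016394	A	0.195	0.191	0.96	0.10	0.727	0.95	0.790
2	TNP1	rs13387042	G	0.907	0.883	0.77	0.13	0.045	0.93	0.062
2	DIRC3	rs16857609	C	0.376	0.367	1.07	0.09	0.462	1.08	0.977
3	ITPR1/EGOT	rs6762644	G	0.098	0.096	0.97	0.14	0.841	1.07	0.790
3	SLC4A7	rs4973768	A	0.190	0.186	0.97	0.10	0.757	1.11	0.473
3	TGFBR2	rs12493607	G	0.278	0.262	0.91	0.09	0.290	1.06	0.619
4	TET2	rs9790517	A	0.613	0.635	1.09	0.08	0.293	1.05	0.440
4	ADAM29	rs6828523	A	0.275	0.271	0.99	0.09	0.879	0.90	0.729
5	5p12	rs4415084	C	0.441	0.434	0.96	0.08	0.668	1.15	0.087
5	MRPS30	rs10941679	G	0.499	0.519	1.09	0.08	0.289	1.12	0.409
5	MAP3K1	rs889312	C	0.589	0.577	0.96	0.08	0.666	1.05	0.727
5	RAB3C	rs10472076	G	0.247	0.260	1.07	0.09	0.465	1.04	0.500
5	EBF1	rs1432679	G	0.631	0.642	1.05	0.08	0.558	1.07	0.931
6	FOXQ1	rs11242675	A	0.597	0.633	1.15	0.08	0.088	NA	NA
6	ECHDC1/RNF146	rs2180341	G	0.181	0.198	1.09	0.10	0.365	1.31	0.100
6	RANBP9	rs204247	G	0.588	0.611	1.10	0.08	0.248	1.05	0.911
6	FAM46A	rs17529111	G	0.218	0.206	0.92	0.10	0.404	1.06	0.675
6	ESR1	rs3757318	A	0.276	0.316	1.20	0.09	0.039	1.04	0.790
6	ESR1	rs2046210	A	0.380	0.434	1.25	0.08	0.008	1.27	0.970
7	ARHGEF5	rs720475	A	0.046	0.041	0.90	0.20	0.596	0.94	0.941
8	RPL17P33	rs9693444	A	0.282	0.288	1.04	0.09	0.691	1.07	0.977
8	8q24	rs13281615	G	0.502	0.500	0.99	0.08	0.872	1.07	0.215
8	8q24	rs1562430	C	0.181	0.184	1.03	0.11	0.820	0.87	0.273
9	CDKN2A	rs1011970	A	0.096	0.095	0.98	0.14	0.875	1.07	0.639
9	KLF4	rs10759243	A	0.431	0.476	1.20	0.08	0.027	1.06	0.790
9	KLF4	rs865686	C	0.057	0.067	1.19	0.16	0.275	0.90	0.150
10	ZNF365	rs10822013	T	0.500	0.517	1.07	0.08	0.409	1.08	0.387
10	ZNF365	rs10995190	A	0.012	0.013	1.14	0.36	0.713	1.06	0.350
10	ZMIZ1	rs704010	A	0.369	0.397	1.12	0.08	0.169	1.08	0.473
10	FGFR2	rs1219648	G	0.404	0.427	1.08	0.08	0.343	1.14	0.560
10	FGFR2	rs2981582	A	0.338	0.370	1.14	0.08	0.128	1.26	0.451
11	LSP1	rs3817198	G	0.095	0.108	1.14	0.13	0.311	1.07	0.931
11	DKFZp761E198/OVOL1/SNX32/CFL1	rs3903072	A	0.210	0.175	0.81	0.10	0.039	0.95	0.268
11	BARX2	rs11820646	A	0.489	0.509	1.09	0.08	0.278	0.95	0.574
12	ATF7IP	rs12422552	C	0.273	0.325	1.29	0.09	0.004	1.06	0.128
12	PTHLH	rs10771399	G	0.192	0.173	0.88	0.11	0.221	0.86	0.729
12	NTN4	rs17356907	G	0.253	0.247	0.98	0.09	0.839	0.91	0.604
14	PAX9/SLC25A21	rs2236007	A	0.297	0.255	0.83	0.09	0.031	0.92	0.469
14	CCDC88C	rs941764	G	0.126	0.140	1.13	0.12	0.308	1.06	0.931
16	TOX3	rs4784227	T	0.245	0.274	1.17	0.09	0.098	1.23	0.574
16	TOX3	rs3112612	G	0.228	0.210	0.90	0.10	0.300	1.13	0.066
16	CDYL2	rs13329835	G	0.053	0.054	1.02	0.18	0.938	1.09	0.351
16	MIR1972-2/FTO	rs17817449	C	0.140	0.118	0.83	0.12	0.134	0.93	0.079
18	AQP4	rs527616	G	0.267	0.266	0.99	0.09	0.951	0.98	0.805
18	CHST9	rs1436904	C	0.486	0.509	1.09	0.08	0.287	0.96	0.225
19	C19orf61/KCNN4/LYPD5/ZNF283	rs3760982	A	0.136	0.148	1.10	0.12	0.437	1.06	0.994
21	NRIP1	rs2823093	A	0.035	0.032	0.90	0.23	0.631	0.92	0.994
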