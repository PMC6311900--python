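snp	chr	pos	genes	ea	nea	eaf	beta_pd	se_pd	pval_pd	beta_ad	se_ad	pval_ad
rs10797576	1	232664611	SIPA1L2	T	C	0.127	0.113	0.014	8.41E-13	0.006	0.022	0.795
rs10906923	10	15569598	FAM171A1	A	C	0.461	0.073	0.014	1.35E-8	-0.033	0.017	0.051
rs11060180	12	123303586	OGFOD2	A	G	0.748	0.105	0.011	2.05E-20	0.032	0.019	0.081
rs11158026	14	55348869	GCH1	C	T	0.490	0.094	0.011	4.30E-16	-0.002	0.017	0.894
rs115185635	3	87520857	CHMP2B	C	G	0.012	0.191	0.048	1.22E-4	-0.022	0.058	0.702
rs11724635	4	15737101	FAM200B,CD38	A	C	0.408	0.105	0.011	1.22E-19	-0.032	0.016	0.040
rs117896735	10	121536327	BAG3	A	G	0.004	0.501	0.057	2.23E-19	0.133	0.086	0.119
rs12456492	18	40673380	SYT4	G	A	0.330	0.095	0.012	5.56E-16	0.009	0.017	0.589
rs12497850	3	48748989	NCKIPSD,CDC71	T	G	0.731	0.073	0.014	9.16E-9	0.028	0.017	0.088
rs12637471	3	182762437	MCCC1	G	A	0.663	0.163	0.015	2.11E-30	0.002	0.019	0.909
rs13294100	9	17579690	SH3GL2	G	T	0.457	0.083	0.014	4.84E-13	0.013	0.017	0.453
rs14235	16	31121793	ZNF646,KAT8	A	G	0.359	0.077	0.009	5.44E-12	0.041	0.016	0.011
rs1474055	2	169110394	STK39	T	C	0.201	0.186	0.018	5.68E-26	0.004	0.024	0.881
rs1555399	14	67984370	TMEM229B	T	A	0.607	0.086	0.012	9.61E-11	-0.021	0.016	0.194
rs199347	7	23293746	KLHL7,NUPL2,GPNMB	A	G	0.483	0.094	0.011	3.51E-18	-0.033	0.016	0.039
rs2280104	8	22525980	SORBS3,PDLIM2,C8orf58,BIN3	T	C	0.265	0.068	0.012	2.53E-8	-0.002	0.016	0.923
rs2414739	15	61994134	VPS13C	A	G	0.679	0.094	0.011	3.94E-14	-8.00E-04	0.017	0.964
rs2694528	5	60273923	ELOVL7	C	A	0.135	0.140	0.020	4.84E-15	-0.028	0.027	0.305
rs2740594	8	11707174	CTSB	A	G	0.893	0.086	0.012	5.91E-12	0.002	0.018	0.926
rs329648	11	133765367	MIR4697	T	C	0.465	0.086	0.012	1.11E-13	-0.007	0.018	0.701
rs34043159	2	102413116	IL1R2	C	T	0.332	0.077	0.009	5.48E-11	0.006	0.016	0.695
rs34311866	4	951947	TMEM175,DGKQ	C	T	0.140	0.207	0.014	1.47E-50	0.009	0.021	0.685
rs353116	2	166133632	SCN3A	C	T	0.557	0.062	0.011	2.98E-8	0.038	0.016	0.021
rs356182	4	90626111	SNCA	G	A	0.404	0.285	0.012	5.21E-123	-0.056	0.017	0.001
rs35749011	1	155135036	GBA	A	G	0.005	0.545	0.044	2.59E-35	0.188	0.071	0.008
rs3793947	11	83544472	DLG2	G	A	0.570	0.073	0.011	3.72E-9	-0.010	0.016	0.525
rs4073221	3	18277488	SATB1	G	T	0.062	0.095	0.016	1.57E-8	0.007	0.023	0.754
rs4653767	1	226916078	ITPKB	T	C	0.726	0.083	0.011	1.63E-11	-0.005	0.017	0.756
rs4784227	16	52599188	TOX3	T	C	0.200	0.086	0.014	9.75E-11	-0.010	0.018	0.580
rs591323	8	16697091	MICU3	G	A	0.635	0.094	0.014	2.38E-11	-0.002	0.018	0.930
rs62120679	19	2363319	LSM7	T	C	0.426	0.077	0.014	6.64E-7	-0.004	0.022	0.843
rs6430538	2	135539967	TMEM163,CCNT2	C	T	0.189	0.117	0.011	8.24E-24	-0.047	0.017	0.006
rs6812193	4	77198986	FAM47E	C	T	0.687	0.083	0.011	1.43E-14	-0.017	0.016	0.310
rs76904798	12	40614434	LRRK2	T	C	0.132	0.140	0.015	1.21E-19	-0.016	0.022	0.483
rs78738012	4	114360372	ANK2,CAMK2D	C	T	0.039	0.122	0.018	4.78E-11	-0.012	0.029	0.680
rs8005172	14	88472612	GALC	T	C	0.434	0.077	0.012	8.77E-11	-0.021	0.016	0.171
rs8118008	20	3168166	DDRGK1	A	G	0.540	0.068	0.012	1.99E-6	0.014	0.018	0.432
rs823118	1	205723572	NUCKS1,SLC41A1	T	C	0.411	0.117	0.011	1.12E-23	-0.003	0.016	0.846
rs9468199	6	27681215	ZNF184	A	G	0.300	0.104	0.014	1.46E-12	0.044	0.022	0.046
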