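snp	chr	pos	year	source	ancestry	ld_r2	function_class	ea	nea	eaf	or	ci_low	ci_high	pval	source_n
rs356182	4	90626111	2017	Chang_D	European	1	intron	G	A	0.404	1.33	1.30	1.36	5.21E-123	428235
rs356219	4	89716450	2012	Lill_CM	Caucasian	0.76	intron	G	A	0.41	1.29	1.25	1.33	6.00E-65	110000
rs356220	4	89720189	2014	Hill-Burns_EM	European	0.51	intron	T	C	0.364	1.38	1.24	1.52	3.00E-11	8477
rs2736990	4	89757390	2010	Edwards_DL	Caucasian	0.48	intron	G	A	0.52	1.30	1.18	1.43	6.74E-8	4005
rs8180209	4	89723303	2017	Foo_JN	Han_Chinese	NA	intron	A	G	0.07	0.41	NA	NA	1.02E-32	26530
rs11931074	4	89718364	2009	Satake_W	Japanese	NA	intron	G	T	0.36	1.37	1.27	1.48	7.35E-17	4667
rs6532194	4	89859751	2012	Lill_CM	Asian	NA	intergenic	T	C	0.40	1.29	1.20	1.39	4.91E-11	110000
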