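excluded_snp	pval_ivw	pval_weighted_median	pval_egger
rs10797576	0.281	0.600	0.437
rs10906923	0.365	0.653	0.348
rs11060180	0.200	0.598	0.422
rs11158026	0.299	0.660	0.444
rs115185635	0.307	0.654	0.454
rs11724635	0.419	0.653	0.441
rs117896735	0.207	0.597	0.240
rs12456492	0.264	0.599	0.450
rs12497850	0.222	0.594	0.527
rs12637471	0.277	0.608	0.411
rs13294100	0.260	0.597	0.468
rs14235	0.172	0.593	0.547
rs1474055	0.277	0.605	0.406
rs1555399	0.355	0.652	0.408
rs199347	0.404	0.651	0.405
rs2280104	0.299	0.647	0.445
rs2414739	0.295	0.599	0.445
rs2694528	0.341	0.654	0.474
rs2740594	0.290	0.597	0.449
rs329648	0.311	0.654	0.437
rs34043159	0.277	0.596	0.465
rs34311866	0.245	0.608	0.346
rs353116	0.204	0.593	0.606
rs356182	0.991	0.649	0.313
rs35749011	0.117	0.592	0.075
rs3793947	0.320	0.651	0.418
rs4073221	0.283	0.594	0.446
rs4653767	0.307	0.653	0.438
rs4784227	0.318	0.652	0.433
rs591323	0.297	0.596	0.444
rs62120679	0.302	0.649	0.440
rs6430538	0.473	0.648	0.482
rs6812193	0.340	0.653	0.414
rs76904798	0.331	0.656	0.465
rs78738012	0.310	0.652	0.448
rs8005172	0.353	0.652	0.385
rs8118008	0.267	0.594	0.490
rs823118	0.301	0.662	0.442
rs9468199	0.201	0.596	0.422
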