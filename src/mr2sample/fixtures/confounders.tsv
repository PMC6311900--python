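snp	trait	stage	pval
rs11343	years_of_education	1	1.20E-4
rs17649553	years_of_education	1	2.33E-07
rs9275326	vitamin_C	2	6.42E-04
rs9275326	vitamin_B9	2	1.95E-09
rs9275326	mineral_supplements	2	2.63E-06
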