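trait	snp	chr	pos	ea	nea	eaf	beta	se	pval
pd	rs143918452	6	133210361	A	G	0.021	0.491	0.075	6.00E-11
pd	rs11343	7	66009851	T	G	0.348	0.092	0.012	1.80E-14
pd	rs17649553	17	43994648	T	C	0.219	0.135	0.012	9.00E-29
pd	rs9275326	6	32666660	T	C	0.094	0.112	0.015	8.00E-14
ad	rs11343	7	66009851	T	G	0.351	-0.011	0.016	0.492
ad	rs17649553	17	43994648	T	C	0.216	0.013	0.017	0.444
ad	rs9275326	6	32666660	T	C	0.092	-0.021	0.024	0.382
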