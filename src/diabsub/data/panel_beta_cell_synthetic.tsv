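variant_id	risk_allele	other_allele	weight	freq
rs22229842	C	G	0.1326	0.336
rs98897124	A	C	0.1054	0.562
rs28144142	T	G	0.0975	0.506
rs65314302	T	G	0.1843	0.418
rs64806835	A	T	0.2016	0.429
rs29048255	T	C	0.0668	0.328
rs38729110	G	C	0.139	0.375
rs25597829	C	T	0.0798	0.418
rs33336376	T	C	0.0858	0.657
rs68604374	G	C	0.119	0.486
rs42754488	A	T	0.0549	0.38
rs26797876	T	C	0.2123	0.572
rs77898436	T	A	0.0421	0.58
rs7585156	T	C	0.1059	0.554
rs51835824	A	G	0.0814	0.588
rs11254971	T	C	0.1905	0.466
rs71853017	C	T	0.1927	0.655
rs29378014	T	A	0.1957	0.394
rs8767452	A	C	0.0908	0.558
rs7537250	C	G	0.1136	0.485
rs78371373	A	T	0.0965	0.333
rs43119922	T	G	0.1431	0.308
rs27443325	C	A	0.0813	0.578
rs63748959	G	C	0.0798	0.316
rs62156513	G	C	0.0668	0.668
rs14789785	G	T	0.161	0.641
rs15152100	A	G	0.2121	0.555
rs85277441	T	A	0.198	0.493
rs89410945	G	T	0.0586	0.494
rs94015159	A	T	0.0729	0.456
rs87610251	C	A	0.1267	0.539
rs13624039	T	G	0.1032	0.401
rs30618466	A	G	0.1102	0.495
rs27705572	C	T	0.1158	0.555
rs99930218	G	C	0.1448	0.508
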