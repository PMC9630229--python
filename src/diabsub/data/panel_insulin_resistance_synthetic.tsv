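variant_id	risk_allele	other_allele	weight	freq
rs88691291	A	G	0.1711	0.458
rs13972692	C	A	0.1077	0.432
rs39851632	G	A	0.0689	0.519
rs46690547	G	A	0.1095	0.663
rs34000996	G	T	0.0932	0.32
rs56131514	G	C	0.136	0.514
rs42769665	T	C	0.1246	0.455
rs71267803	G	A	0.1987	0.329
rs64528766	G	C	0.0962	0.587
rs59072284	G	C	0.1302	0.615
rs13282503	C	A	0.1103	0.556
rs51112441	T	C	0.0426	0.62
rs81550455	C	T	0.1517	0.535
rs8212342	T	C	0.2011	0.584
rs38741924	C	A	0.1168	0.375
rs83159107	C	G	0.1499	0.632
rs99430966	G	A	0.1661	0.517
rs52692293	C	T	0.0809	0.499
rs71745515	T	C	0.1127	0.546
rs70802643	T	A	0.0892	0.638
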