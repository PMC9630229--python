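variant_id	risk_allele	other_allele	weight	freq
rs46411529	A	T	0.4224	0.574
rs27003879	A	T	0.3569	0.656
rs84800996	C	A	0.3807	0.549
rs23329133	A	G	0.3415	0.488
rs74812920	T	C	0.2101	0.342
rs49672141	G	C	0.1853	0.382
rs93680273	A	G	0.1321	0.63
rs66582515	C	A	0.1532	0.635
rs71552167	T	A	0.1465	0.566
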