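gene_id	transcript	mean	stdev	high	low	printed_high_low_ratio	printed_cv_percent
P1	ppa004809	64	12	83	44	1.89	18
P2	ppa009591	36	5	46	27	1.70	15
P3	ppa005747	90	11	112	70	1.60	12
P4	ppa017220	121	21	153	77	1.99	18
P5	ppa006628	96	12	114	72	1.58	12
P6	ppa004662	45	8	59	33	1.79	18
P7	ppa002552	93	13	117	70	1.67	14
P8	ppa0056076	90	12	114	66	1.73	13
P9	ppa002787	212	33	269	155	1.74	15
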