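gene_id	transcript	mean	stdev	high	low	printed_high_low_ratio	printed_cv_percent
REF1	ppa007242	1378	445.1	2582	817.0	3.16	32
REF2	ppa002435	61.85	11.72	91.46	47.18	1.94	19
REF3	ppa001367	176.3	43.46	249.4	112.9	2.21	25
REF4	ppa001368	587.9	159.9	858.5	361.0	2.38	27
REF5	ppa020696	1.13	0.67	2.35	0	NA	59
REF6	ppa008227	1523	261.2	2112	1079	1.96	17
REF7	ppa012884	4.14	1.93	8.62	1.08	7.95	47
REF8	ppa008812	115.1	33.58	169.1	51.54	3.28	29
REF9	ppa016873	7.77	2.09	12.15	4.05	3.00	27
REF10	ppa011512	753.8	190.5	1101	425.7	2.59	25
REF11	ppa005642	191.5	60.59	321.15	100.80	3.19	32
REF12	ppa005644	260.4	133.4	568.33	108.03	5.26	51
REF13	ppa007117	325.3	85.33	492.26	202.82	2.43	26
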