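gene	gene_length	loeuf	ac_cases	ac_controls	p_published	q_published
PIK3CD	6333	0.20	2	68	2e-05	0.04
MTOR	12163	0.18	4	252	4e-05	0.05
RAE1	5642	0.19	2	18	8e-05	0.08
ZBTB21	8062	0.25	3	120	2e-04	0.12
ESAM	2920	0.59	2	37	2e-04	0.12
TMEM192	10182	1.29	2	30	3e-04	0.13
CLTCL1	10052	0.80	6	438	3e-04	0.13
NFRKB	6335	0.37	3	233	3e-04	0.13
EP300	11692	0.10	3	266	4e-04	0.15
MTSS2	4986	0.31	4	206	4e-04	0.15
SETD2	10245	0.21	5	505	6e-04	0.16
SMC2	6470	0.23	4	131	6e-04	0.17
EBF4	3541	0.70	3	72	8e-04	0.18
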