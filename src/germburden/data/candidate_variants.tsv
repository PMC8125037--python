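chrom	pos	ref	alt	gene	consequence	cadd_phred	clinvar	mq	af_nc_nwe	af_popmax
1	9715647	A	G	PIK3CD	missense	25	.	.	.	.
1	9715709	C	T	PIK3CD	missense	35	.	.	3e-05	9e-06
1	11130641	G	A	MTOR	missense	22.8	.	.	0.0009	0.0007
1	11238522	G	A	MTOR	missense	28.9	.	.	.	5e-05
1	11248030	T	A	MTOR	missense	23.1	.	.	.	0.0003
20	57365381	C	T	RAE1	missense	31	.	.	.	6e-05
20	57365432	A	G	RAE1	missense	20.6	.	.	.	.
21	41991340	G	A	ZBTB21	missense	25.3	.	.	.	0.0007
21	41992058	G	A	ZBTB21	missense	26.5	.	.	0.0001	0.0001
21	41992762	C	T	ZBTB21	missense	30	.	.	5e-05	4e-05
11	124753942	G	A	ESAM	missense	34	.	.	5e-05	3e-05
11	124754658	G	A	ESAM	missense	33	.	.	8e-05	0.0002
4	165103020	T	G	TMEM192	missense	22.9	.	.	.	.
4	165103021	G	A	TMEM192	stopgain	35	.	.	.	.
22	19210459	C	T	CLTCL1	missense	32	.	.	.	0.001
22	19219929	C	T	CLTCL1	missense	25.5	.	.	0.0002	0.001
22	19224006	T	G	CLTCL1	missense	29.5	.	.	.	9e-06
22	19226346	T	C	CLTCL1	missense	25.5	.	.	0.0003	0.0004
22	19233264	C	A	CLTCL1	missense	23.6	.	.	.	6e-05
22	19234672	A	G	CLTCL1	missense	25.3	.	.	.	.
11	129872957	G	A	NFRKB	missense	31	.	.	.	.
11	129874521	G	A	NFRKB	missense	23.9	.	.	.	4e-05
11	129884816	G	A	NFRKB	missense	22.9	.	.	.	6e-05
22	41117808	C	T	EP300	missense	21.3	.	.	.	.
22	41137724	C	T	EP300	missense	24.9	.	.	.	.
22	41149147	C	T	EP300	missense	23.2	.	.	8e-05	0.0002
16	70663765	G	A	MTSS2	missense	24.5	.	.	0.0002	0.001
16	70664615	T	C	MTSS2	missense	23.9	.	.	0.0002	0.002
16	70665044	C	T	MTSS2	missense	26.1	.	.	5e-05	0.002
16	70679820	C	G	MTSS2	missense	29.1	.	.	.	9e-06
3	47046509	C	T	SETD2	missense	33	.	.	3e-05	9e-06
3	47046543	G	T	SETD2	missense	25.9	.	.	.	.
3	47084114	A	G	SETD2	missense	25.3	.	.	0.001	0.002
3	47121407	T	C	SETD2	missense	23.6	.	.	0.002	0.002
3	47123308	C	G	SETD2	missense	25.8	.	.	.	.
9	104114033	C	T	SMC2	missense	20.6	.	.	.	.
9	104125007	G	A	SMC2	missense	23	.	.	0.0002	0.0009
9	104139220	A	G	SMC2	missense	23.9	.	.	.	.
20	2706020	G	A	EBF4	missense	21	.	.	6e-05	0.0001
20	2706211	C	A	EBF4	missense	23.3	.	.	.	.
20	2755749	G	A	EBF4	missense	32	.	.	.	.
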