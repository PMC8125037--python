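chrom	pos	end	ref	alt	gene	rsid	transcript	cdna	protein	consequence	cadd	af_cases	af_frex	af_nc_nwe	af_popmax	series
1	9715647	9715647	A	G	PIK3CD	.	NM_005026	c.A248G	p.E83G	missense	25	0.01	.	.	.	.
1	9715709	9715709	C	T	PIK3CD	.	NM_005026	c.C310T	p.R104C	missense	35	0.01	.	3e-05	9e-06	.
1	11130641	11130641	G	A	MTOR	rs142403193	NM_004958	c.C5501T	p.T1834M	missense	22.8	0.02	.	9e-04	7e-04	SKCM(2)
1	11238522	11238522	G	A	MTOR	rs751242124	NM_004958	c.C1882T	p.R628C	missense	28.9	0.01	.	.	5e-05	.
1	11248030	11248030	T	A	MTOR	rs761323069	NM_004958	c.A905T	p.D302V	missense	23.1	0.01	.	.	3e-04	.
20	57365381	57365381	C	T	RAE1	rs755561880	NM_003610	c.C314T	p.S105L	missense	31	0.01	.	.	6e-05	.
20	57365432	57365432	A	G	RAE1	.	NM_003610	c.A365G	p.Q122R	missense	20.6	0.01	.	.	.	.
21	41991340	41991340	G	A	ZBTB21	rs368359632	NM_001098402	c.C2756T	p.T919M	missense	25.3	0.01	.	.	7e-04	.
21	41992058	41992058	G	A	ZBTB21	rs371004245	NM_001098402	c.C2038T	p.R680C	missense	26.5	0.01	.	1e-04	1e-04	.
21	41992762	41992762	C	T	ZBTB21	.	NM_001098402	c.G1334A	p.R445H	missense	30	0.01	.	5e-05	4e-05	.
11	124753942	124753942	G	A	ESAM	rs760488150	NM_138961	c.C877T	p.R293W	missense	34	0.01	.	5e-05	3e-05	.
11	124754658	124754658	G	A	ESAM	rs200924772	NM_138961	c.C713T	p.T238M	missense	33	0.01	9e-04	8e-05	2e-04	.
4	165103020	165103020	T	G	TMEM192	.	NM_001100389	c.A104C	p.Q35P	missense	22.9	0.01	.	.	.	.
4	165103021	165103021	G	A	TMEM192	.	NM_001100389	c.C103T	p.Q35X	stopgain	35	0.01	.	.	.	.
22	19210459	19210459	C	T	CLTCL1	rs781878409	NM_007098	c.G3116A	p.R1039Q	missense	32	0.01	.	.	1e-03	.
22	19219929	19219929	C	T	CLTCL1	rs188611399	NM_007098	c.G2875A	p.V959I	missense	25.5	0.01	.	2e-04	1e-03	KIRP(2)
22	19224006	19224006	T	G	CLTCL1	rs782728804	NM_007098	c.A2177C	p.D726A	missense	29.5	0.01	.	.	9e-06	.
22	19226346	19226346	T	C	CLTCL1	rs201280856	NM_007098	c.A1820G	p.H607R	missense	25.5	0.01	.	3e-04	4e-04	.
22	19233264	19233264	C	A	CLTCL1	rs782774942	NM_007098	c.G1423T	p.A475S	missense	23.6	0.01	.	.	6e-05	.
22	19234672	19234672	A	G	CLTCL1	.	NM_007098	c.T1004C	p.V335A	missense	25.3	0.01	.	.	.	.
11	129872957	129872957	G	A	NFRKB	.	NM_006165	c.C2765T	p.P922L	missense	31	0.01	.	.	.	.
11	129874521	129874521	G	A	NFRKB	rs200192480	NM_006165	c.C2113T	p.P705S	missense	23.9	0.01	.	.	4e-05	fNTMC(1 family)
11	129884816	129884816	G	A	NFRKB	rs755726394	NM_006165	c.C746T	p.A249V	missense	22.9	0.01	.	.	6e-05	.
22	41117808	41117808	C	T	EP300	.	NM_001429	c.C716T	p.P239L	missense	21.3	0.01	.	.	.	.
22	41137724	41137724	C	T	EP300	.	NM_001429	c.C1694T	p.T565I	missense	24.9	0.01	.	.	.	.
22	41149147	41149147	C	T	EP300	rs201480900	NM_001429	c.C2351T	p.P784L	missense	23.2	0.01	.	8e-05	2e-04	SKCM(1)
16	70663765	70663765	G	A	MTSS2	rs749003640	NM_138383	c.C2156T	p.P719L	missense	24.5	0.01	.	2e-04	1e-03	KIRP(1)
16	70664615	70664615	T	C	MTSS2	rs147433916	NM_138383	c.A1454G	p.D485G	missense	23.9	0.01	2e-03	2e-04	2e-03	SKCM(1)
16	70665044	70665044	C	T	MTSS2	rs549028223	NM_138383	c.G1181A	p.R394Q	missense	26.1	0.01	.	5e-05	2e-03	.
16	70679820	70679820	C	G	MTSS2	rs768341867	NM_138383	c.G348C	p.K116N	missense	29.1	0.01	.	.	9e-06	.
3	47046509	47046509	C	T	SETD2	rs766193321	NM_001349370	c.G6944A	p.G2315E	missense	33	0.01	.	3e-05	9e-06	.
3	47046543	47046543	G	T	SETD2	.	NM_001349370	c.C6910A	p.P2304T	missense	25.9	0.01	.	.	.	.
3	47084114	47084114	A	G	SETD2	rs148097513	NM_001349370	c.T5534C	p.M1845T	missense	25.3	0.01	9e-04	1e-03	2e-03	KIRC(3);KIRP(1);SKCM(1)
3	47121407	47121407	T	C	SETD2	rs114719990	NM_001349370	c.A3097G	p.T1033A	missense	23.6	0.01	2e-03	2e-03	2e-03	SKCM(3);KIRP(1)
3	47123308	47123308	C	G	SETD2	.	NM_001349370	c.G1196C	p.R399T	missense	25.8	0.01	.	.	.	.
9	104114033	104114033	C	T	SMC2	.	NM_001042550	c.C1484T	p.T495I	missense	20.6	0.01	.	.	.	.
9	104125007	104125007	G	A	SMC2	rs147960477	NM_001042550	c.G2353A	p.A785T	missense	23	0.02	9e-04	2e-04	9e-04	.
9	104139220	104139220	A	G	SMC2	.	NM_001042550	c.A3499G	p.T1167A	missense	23.9	0.01	.	.	.	.
20	2706020	2706020	G	A	EBF4	rs202097996	NM_001110514	c.G329A	p.R110Q	missense	21	0.01	9e-04	6e-05	1e-04	.
20	2706211	2706211	C	A	EBF4	.	NM_001110514	c.C349A	p.L117M	missense	23.3	0.01	.	.	.	.
20	2755749	2755749	G	A	EBF4	rs369331115	NM_001110514	c.G1651A	p.A551T	missense	32	0.01	.	.	.	.
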