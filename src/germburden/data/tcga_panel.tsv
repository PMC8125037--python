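chrom	pos	ref	alt	series	occurrences
1	11130641	G	A	SKCM	2
22	19219929	C	T	KIRP	2
22	41149147	C	T	SKCM	1
16	70663765	G	A	KIRP	1
16	70664615	T	C	SKCM	1
3	47084114	A	G	KIRC	3
3	47084114	A	G	KIRP	1
3	47084114	A	G	SKCM	1
3	47121407	T	C	SKCM	3
3	47121407	T	C	KIRP	1
11	129874521	G	A	fNTMC	1
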