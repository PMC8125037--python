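chrom	pos	ref	alt	af
11	124754658	G	A	9e-04
16	70664615	T	C	2e-03
3	47084114	A	G	9e-04
3	47121407	T	C	2e-03
9	104125007	G	A	9e-04
20	2706020	G	A	9e-04
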