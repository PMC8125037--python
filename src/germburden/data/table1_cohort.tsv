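key	value
n_patients	125
n_male	80
n_female	45
age_first_melanoma_mean	57.3
age_first_rcc_mean	58.8
n_melanoma_cutaneous	158
n_rcc_clear_cell	93
n_rcc_papillary	16
n_rcc_chromophobe	8
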