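group	n_cohorts	n_samples	n_female	n_male
non_small_cell_lung_cancer	10	1338	594	744
colon_cancer	7	769	358	411
other_cancer	5	200	64	136
non_cancer	7	408	219	189
breast_cancer	8	1373	1373	0
ovarian_cancer	4	426	426	0
prostate_cancer	4	399	0	399
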