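trait	Lasso	Ridge	BLUP	GBM	RF	SVM
Yield (drought)	0.023	0.060	0.217	0.051	0.172	0.219
Yield (irrigated)	0.084	0.162	0.253	0.132	0.184	0.258
TKW	0.172	0.240	0.277	0.218	0.242	0.304
DTH	0.292	0.325	0.381	0.325	0.358	0.394
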