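sex	outcome	term	coefficient	variant
male	fev1	intercept_young	-25.857	both
male	fev1	intercept_old	-25.144	both
male	fev1	age_slope_young	0.0285	both
male	fev1	age_slope_old	-0.0288	both
male	fev1	height_linear	0.296	both
male	fev1	height_quadratic_young	-0.000728	both
male	fev1	height_quadratic_old	-0.000728	both
male	fev1	r_squared	0.73	both
male	fev1	residual_sd	0.38	both
female	fev1	intercept_young	-2.546	both
female	fev1	intercept_old	-2.342	both
female	fev1	age_slope_young	0.0082	both
female	fev1	age_slope_old	-0.0232	both
female	fev1	height_linear	0.0343	both
female	fev1	r_squared	0.80	both
female	fev1	residual_sd	0.28	both
male	ln_fvc	intercept_young	-13.518	both
male	ln_fvc	intercept_old	-13.094	both
male	ln_fvc	age_slope_young	0.0196	both
male	ln_fvc	age_slope_old	-0.0070	both
male	ln_fvc	height_linear	0.156	both
male	ln_fvc	height_quadratic_young	-0.00041	corrected
male	ln_fvc	height_quadratic_young	0.00041	as_printed
male	ln_fvc	height_quadratic_old	-0.00041	both
male	ln_fvc	weight_linear	-0.00138	both
male	ln_fvc	r_squared	0.69	both
male	ln_fvc	residual_sd	0.12	both
female	ln_fvc	intercept_young	-11.355	both
female	ln_fvc	intercept_old	-10.509	both
female	ln_fvc	age_slope_young	0.0338	both
female	ln_fvc	age_slope_old	-0.0079	both
female	ln_fvc	height_linear	0.130	both
female	ln_fvc	height_quadratic_young	-0.00035	both
female	ln_fvc	height_quadratic_old	-0.00035	both
female	ln_fvc	weight_linear	-0.00107	both
female	ln_fvc	r_squared	0.74	both
female	ln_fvc	residual_sd	0.13	both
male	ratio	intercept	86.07	both
male	ratio	age_linear	-0.0707	both
male	ratio	r_squared	0.03	both
male	ratio	residual_sd	6.82	both
female	ratio	intercept	105.38	both
female	ratio	age_linear	-0.7852	both
female	ratio	age_quadratic	0.0069	both
female	ratio	r_squared	0.08	both
female	ratio	residual_sd	8.45	both
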