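sex	outcome	height_slope_per_m	age_slope_per_yr	intercept	source_label
male	fev1	4.30	-0.029	-2.49	ECSC/ERS 1993 summary equations, adults
male	fvc	5.76	-0.026	-4.34	ECSC/ERS 1993 summary equations, adults
male	ratio	0.0	-0.18	87.21	ECSC/ERS 1993 summary equations, adults
female	fev1	3.95	-0.025	-2.60	ECSC/ERS 1993 summary equations, adults
female	fvc	4.43	-0.026	-2.89	ECSC/ERS 1993 summary equations, adults
female	ratio	0.0	-0.19	89.10	ECSC/ERS 1993 summary equations, adults
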