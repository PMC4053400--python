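energy	8CA-wild	8CA-mutant	F8A-wild	F8A-mutant	I4A-wild	I4A-mutant
dE_vdw	-33.35±0.19	-32.59±0.16	-33.29±0.12	-32.74±0.21	-41.61±0.22	-40.33±0.18
dE_c	-57.40±0.24	-20.84±0.21	-52.04±0.24	-21.34±0.43	-59.51±0.23	-28.08±0.28
gamma_dMSA	-7.55±0.22	-7.29±0.15	-7.89±0.02	-7.74±0.05	-8.79±0.02	-8.05±0.04
dG_R	43.81±0.03	24.93±0.02	40.84±0.22	22.45±0.22	45.88±0.17	27.44±0.18
dG_bind	-8.63±0.04	-6.59±0.02	-8.42±0.02	-6.97±0.04	-9.58±0.03	-7.90±0.03
dG_exp	-8.52		-8.46		-8.69
ddG_bind		2.04		1.45		2.18
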