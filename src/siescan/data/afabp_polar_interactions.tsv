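complex	residue	wild	mutant
8CA	R78	-5.93±0.45	-6.20±0.38
8CA	R106	-10.21±0.47	-14.12±0.24
8CA	R126	-21.96±0.72	-0.10±0.05
F8A	R78	-6.08±0.31	-6.99±0.41
F8A	R106	-8.01±0.52	-13.30±0.47
F8A	R126	-20.01±0.66	-0.01±0.07
I4A	R78	-7.56±0.35	-6.45±0.28
I4A	R106	-10.43±0.42	-14.78±0.31
I4A	R126	-23.26±0.51	-0.05±0.04
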