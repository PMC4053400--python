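complex	bond	energy
8CA	O2...R126HE	-0.76±0.11
8CA	O1...R126HH21	-2.50±0.19
8CA	O1...Y128HH	-1.81±0.20
8CA	O2...Y128HH	-0.69±0.12
F8A	O12...R126HE	-1.17±0.14
F8A	O11...R126HH21	-1.77±0.16
F8A	O11...Y128HH	-0.46±0.10
F8A	O12...Y128HH	-2.05±0.18
I4A	O26...R126HE	-1.34±0.13
I4A	O27...R126HH21	-1.80±0.13
I4A	O27...Y128HH	-0.51±0.10
I4A	O26...Y128HH	-2.60±0.15
I4A	H18...S55OG	-0.55±0.12
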