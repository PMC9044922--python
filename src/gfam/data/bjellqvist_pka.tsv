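group	residue	pka
nterm	default	7.50
nterm	A	7.59
nterm	M	7.00
nterm	S	6.93
nterm	P	8.36
nterm	T	6.82
nterm	V	7.44
nterm	E	7.70
cterm	default	3.55
cterm	D	4.55
cterm	E	4.75
positive	K	10.00
positive	R	12.00
positive	H	5.98
negative	D	4.05
negative	E	4.45
negative	C	9.00
negative	Y	10.00
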