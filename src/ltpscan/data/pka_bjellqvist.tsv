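group	pka	charge
n_term	7.50	positive
c_term	3.55	negative
D	4.05	negative
E	4.45	negative
C	9.00	negative
Y	10.00	negative
H	5.98	positive
K	10.00	positive
R	12.00	positive
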