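element	category
P-box	A
CGTCA-motif	A
TGACG-motif	A
ERE	A
TGA-element	A
TATC-box	A
Box-W1	B
WUN-motif	B
TC-rich repeats	B
LTR	B
MBS	B
HSE	B
TCA-element	B
ARE	C
CCGTCC-box	C
CAT-box	C
circadian	C
5UTR Py-rich stretch	C
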