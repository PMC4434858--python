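compound	A	B	C	D	F	G	H
A	0	1	0	0	0	0	0
B	0	0	1	0	0	0	0
C	0	0	0	0	0	0	0
D	0	0	0	0	0	0	0
F	0	0	0	1	0	1	0
G	0	0	0	0	0	0	1
H	0	0	0	0	1	0	0
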