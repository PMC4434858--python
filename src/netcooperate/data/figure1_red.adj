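compound	A	F	W	Y	Z
A	0	0	0	0	1
F	0	0	0	1	0
W	1	0	0	0	0
Y	0	0	0	0	0
Z	0	0	0	0	0
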