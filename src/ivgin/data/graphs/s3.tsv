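# latent: U1 U2
Z1	X
Z2	X
Z3	Z1
Z3	Y
U1	Z3
U1	X
U2	X
U2	Y
X	Y
X	Z4
Y	Z4
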