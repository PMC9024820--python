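# latent: U1
Z1	X
Z2	X
Z3	X
U1	Z1
U1	X
U1	Y
X	Y
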