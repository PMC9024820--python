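# latent: U1
W1	Z
W1	Y
Z	X
U1	X
U1	Y
X	Y
Y	W2
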