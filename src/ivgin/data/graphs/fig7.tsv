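# latent: U1 U2
U1	Z
U1	U2
U2	X
U2	Y
X	Y
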