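# synthetic stand-in for oscillatory-hypoxia-downregulated genes (user-supplied in practice)
OSCN01
OSCN02
OSCN03
OSCN04
OSCN05
OSCN06
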