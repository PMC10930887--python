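# synthetic stand-in for oscillatory-hypoxia-upregulated genes (user-supplied in practice)
OSCP01
OSCP02
OSCP03
OSCP04
OSCP05
OSCP06
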