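# illustrative senescence markers (placeholder, non-authoritative)
CDKN1A
CDKN2A
TP53
GLB1
SERPINE1
LMNB1
MKI67
TRP53BP1
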