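# illustrative SASP factors (placeholder, non-authoritative)
IL6
IL1A
IL1B
CXCL8
CCL2
MMP1
MMP3
IGFBP3
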