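# Illustrative gene sets

Small placeholder lists for demos and tests, one HGNC symbol per line.

These are **not authoritative signatures**. The senescence and SASP lists are
a handful of widely cited marker genes; the oscillatory-hypoxia lists
(`osc_pos`, `osc_neg`) are synthetic stand-ins — the real sets are defined in
prior published work and must be supplied by the user for any scientific use.
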