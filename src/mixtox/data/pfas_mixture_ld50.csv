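pfos_uM,pfoa_ld50_uM
68,16.5
38,29
22,29.5
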