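compound,ld50_uM,ec50_uM
PFOS,53,11
PFOA,187.5,29.5
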