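compound,re_wb,re_rob,re_yolk,rd
S-CY3A,0.15,0.35,0.08,0.24
S-CY5.5A,0,0,0,0.19
S-CY5A,0,0,0,0.18
FAMA,0.05,0.12,0.02,0.32
TAMRA,0.19,0.25,0.17,0.28
R6GA,0.10,0.39,0,0.26
CY3A,1.11,1.99,0.93,0.17
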