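symbol	compartments
MEG3	nucleus
CRNDE	nucleus
SNHG20	nucleus
LINP1	cytoplasm;perinuclear
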