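symbol	compartments
FMR2	cytoplasm
hnRNP A2	nucleoplasm
Nucleolin	nucleoplasm
DHX36	nucleoplasm;cytoplasm
SRSF1	nucleoplasm
SRSF9	nucleoplasm
TLS	nucleoplasm
TRF2	nucleoplasm
PTEN	nucleoplasm;cytosol
SMAD4	nucleoplasm;cytosol
TP53	nucleoplasm
CDKN2A	nucleoli
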