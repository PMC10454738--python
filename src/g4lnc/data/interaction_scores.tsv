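lncrna	protein	protein_transcript	score	cancer_type
LINP1	PTEN	PTEN-001	213.74	CSCC and EA
LINP1	PTEN	PTEN-001	213.74	CSCC and EA
LINP1	TP53	TP53-001	165.3	CSCC and EA
MEG3	SMAD4	SMAD4-001	308.18	CSCC and EA
MEG3	TP53	TP53-001	249.83	CSCC and EA
CRNDE	TP53	TP53-001	106.82	CSCC and EA
CRNDE	TP53	TP53-001	106.82	CSCC and EA
SNHG20	TP53	TP53-001	339.1	CSCC and EA
SNHG20	CDKN2A	CDKN2A-001	273.52	CSCC and EA
SNHG20	TP53	TP53-001	339.1	CSCC and EA
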