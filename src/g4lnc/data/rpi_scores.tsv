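lncrna	protein	rf_score	svm_score
LINP1	FMR2	0.8	0.91
LINP1	hnRNP A2	0.85	0.72
LINP1	Nucleolin	0.9	0.946
LINP1	DHX36	0.8	0.989
LINP1	SRSF1	0.95	0.947
LINP1	SRSF9	0.8	0.922
LINP1	TLS	0.9	0.869
LINP1	TRF2	0.85	0.948
CRNDE	FMR2	0.75	0.99
CRNDE	hnRNP A2	0.9	0.85
CRNDE	Nucleolin	0.95	0.981
CRNDE	DHX36	0.75	0.997
CRNDE	SRSF1	0.95	0.978
CRNDE	SRSF9	0.75	0.968
CRNDE	TLS	0.9	0.945
CRNDE	TRF2	0.8	0.983
SNHG20	FMR2	0.8	0.81
SNHG20	Nucleolin	0.8	0.702
SNHG20	DHX36	0.75	0.961
SNHG20	SRSF1	0.8	0.657
SNHG20	SRSF9	0.7	0.71
SNHG20	TRF2	0.85	0.68
MEG3	FMR2	0.8	0.91
MEG3	hnRNP A2	0.7	0.9
MEG3	Nucleolin	0.85	0.574
MEG3	DHX36	0.7	0.824
MEG3	SRSF1	0.8	0.511
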