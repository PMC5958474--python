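geo_id	gene	fold_change
GSE49598	XPC	2.00
GSE49598	RAD23B	0.43
GSE49598	BRCA2	2.17
GSE49598	LIG3	0.41
GSE49598	MLH3	3.18
GSE49598	MSH2	2.18
GSE11322	BRCA1	5.42
GSE75150	BRCA1	0.43
GSE75150	H2AFX	0.42
GSE75150	CHEK1	0.49
GSE75150	XPC	2.21
GSE75150	LIG1	0.50
GSE75150	MSH3	2.01
GSE39621	BRCA1	2.41
GSE39621	MSH3	0.38
GSE56102	ATRIP	3.11
GSE56102	TP53BP1	0.33
GSE56102	H2AFX	6.37
GSE56102	ATR	6.3
GSE67227	BRCA1	2.33
GSE67227	CHEK1	2.36
GSE67227	LIG1	2.36
GSE67227	RAD51	3.75
GSE40207	MRE11A	0.46
GSE40207	PARP1	2.03
GSE40207	TOPBP1	2.52
GSE40207	H2AFX	2.6
GSE40207	ATR	2.03
GSE40207	UNG	2.18
GSE40207	XPC	2.54
GSE40207	RAD23B	0.33
GSE40207	ERCC4	0.25
GSE40207	LIG1	2.23
GSE40207	XRCC2	0.42
GSE40207	RAD51	2.83
GSE40207	LIG3	0.21
GSE40207	MSH2	3.09
GSE40207	PMS2	2.95
GSE40207	HMGB1	3.19
GSE60413	BRCA1	2.11
GSE60413	ERCC4	0.38
GSE60413	ERCC8	0.43
GSE67676	H2AFX	2.23
GSE67676	LIG1	3.79
GSE67676	RAD51	2.05
GSE13512	ATR	0.46
GSE13512	CHEK1	0.44
GSE13512	OGG1	3.53
GSE13512	XRCC2	2.87
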