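symbol	category	subgroup	aliases	mouse_symbol
RAD17	DDCF	sensor		Rad17
RFC1	DDCF	sensor	RFC	Rfc1
RAD9A	DDCF	sensor	RAD9	Rad9a
RAD1	DDCF	sensor		Rad1
HUS1	DDCF	sensor		Hus1
RPA1	DDCF	sensor	RPA	Rpa1
ATRIP	DDCF	sensor		Atrip
PARP1	DDCF	sensor		Parp1
PARP2	DDCF	sensor		Parp2
MRE11A	DDCF	sensor	MRE11	Mre11a
RAD50	DDCF	sensor		Rad50
NBN	DDCF	sensor	NBS1	Nbn
XRCC6	DDCF	sensor	Ku70	Xrcc6
XRCC5	DDCF	sensor	Ku80	Xrcc5
TP53BP1	DDCF	mediator	53BP1|53BP	Trp53bp1
MDC1	DDCF	mediator		Mdc1
H2AFX	DDCF	mediator	H2AX	H2afx
BRCA1	DDCF	mediator		Brca1
TOPBP1	DDCF	mediator		Topbp1
ATM	DDCF	transducer		Atm
ATR	DDCF	transducer		Atr
PRKDC	DDCF	transducer	DNA-PK|DNAPK	Prkdc
CHEK1	DDCF	transducer		Chek1
CHEK2	DDCF	transducer		Chek2
CDC25A	DDCF	effector		Cdc25a
CDC25C	DDCF	effector		Cdc25c
MGMT	DDRF	DR		Mgmt
ALKBH2	DDRF	DR		Alkbh2
ALKBH3	DDRF	DR		Alkbh3
OGG1	DDRF	BER		Ogg1
NEIL1	DDRF	BER		Neil1
MUTYH	DDRF	BER		Mutyh
UNG	DDRF	BER		Ung
SMUG1	DDRF	BER		Smug1
MPG	DDRF	BER		Mpg
APEX1	DDRF	BER	APE1	Apex1
APEX2	DDRF	BER		Apex2
POLB	DDRF	BER		Polb
PNKP	DDRF	BER		Pnkp
XPC	DDRF	NER		Xpc
RAD23B	DDRF	NER	HR23B	Rad23b
XPA	DDRF	NER		Xpa
ERCC2	DDRF	NER	XPD	Ercc2
ERCC3	DDRF	NER	XPB	Ercc3
ERCC1	DDRF	NER		Ercc1
ERCC5	DDRF	NER	XPG	Ercc5
ERCC4	DDRF	NER	XPF	Ercc4
LIG1	DDRF	NER		Lig1
ERCC8	DDRF	NER	CSA	Ercc8
ERCC6	DDRF	NER	CSB	Ercc6
XRCC2	DDRF	DSBR-HR		Xrcc2
XRCC3	DDRF	DSBR-HR		Xrcc3
BRCA2	DDRF	DSBR-HR		Brca2
RAD52	DDRF	DSBR-HR		Rad52
RAD51	DDRF	DSBR-HR		Rad51
LIG4	DDRF	DSBR-NHEJ		Lig4
NHEJ1	DDRF	DSBR-NHEJ	XLF	Nhej1
XRCC4	DDRF	DSBR-NHEJ		Xrcc4
XRCC1	DDRF	DSBR-MMEJ		Xrcc1
LIG3	DDRF	DSBR-MMEJ		Lig3
MLH1	DDRF	MMR		Mlh1
MLH3	DDRF	MMR		Mlh3
MSH2	DDRF	MMR		Msh2
MSH3	DDRF	MMR		Msh3
MSH6	DDRF	MMR		Msh6
PMS1	DDRF	MMR		Pms1
PMS2	DDRF	MMR		Pms2
HMGB1	DDRF	shared		Hmgb1
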