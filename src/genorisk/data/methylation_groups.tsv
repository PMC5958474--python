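gene	group	index
Rad1	hypo	SAH
Topbp1	hypo	SAH
Mgmt	hypo	SAH
Xrcc3	hypo	SAH
Xrcc4	hypo	SAH
Ercc5	hyper	SAM
Atm	hyper	SAM/SAH
Atr	hyper	SAM/SAH
Mre11a	hyper	SAM/SAH
Chek2	hyper	SAM/SAH
Smug1	hyper	SAM/SAH
Mpg	hyper	SAM/SAH
Ercc8	hyper	SAM/SAH
Ercc2	hyper	SAM/SAH
Lig1	hyper	SAM/SAH
Rad51	hyper	SAM/SAH
Lig3	hyper	SAM/SAH
Rad17	hyper	SAM/SAH
Brca1	hyper	SAM/SAH
Pnkp	hyper	SAM/SAH
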