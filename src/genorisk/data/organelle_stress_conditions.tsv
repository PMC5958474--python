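geo_id	stress	tissue	comparison
GSE49598	ER stress	Mouse embryonic fibroblast	Perk-/- vs. wild-type
GSE11322	ER stress	Mouse telencephalon	Xbp1-/- vs. wild-type
GSE75150	Golgi stress	Mouse embryonic fibroblast	Atf4-/- vs. wild-type
GSE39621	Lysosome stress	Mouse brain	Npc1-/- vs. Npc1+/-
GSE56102	Lysosome stress	Human embryonal carcinoma NTERA2 D/1 cells	VAMP7 knockdown siRNA vs. control
GSE67227	Endosome stress	Mouse liver	Rab5-/- vs. wild-type
GSE40207	Mitochondrial stress	Mouse testis	ClpP-/- vs. wild-type
GSE60413	Mitochondrial stress	Mouse cerebellum	Pink1-/- vs. wild-type
GSE67676	Autophagy	Mouse liver	Atg7 conditional knockout vs. wild-type
GSE13512	Autophagy	Mouse paneth cells	Atg16l1 mutant vs. wild-type
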