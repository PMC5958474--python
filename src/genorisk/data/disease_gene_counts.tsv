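disease	cohort	n_modulated
Coronary artery disease	inflammation	18
Acute coronary syndromes	inflammation	7
Hutchinson-Gilford progeria syndrome	inflammation	13
High glucose (25 mM)	inflammation	9
Type 2 diabetes	inflammation	7
Ovarian carcinomas	cancer	16
Esophageal squamous cell carcinoma	cancer	12
Breast cancer	cancer	12
Non-small cell lung cancers	cancer	12
Burkitt lymphoma	cancer	12
Adult male germ cell tumors	cancer	10
Clear cell renal cell carcinomas	cancer	9
Colorectal carcinoma	cancer	7
Gastric cancer	cancer	7
Crohn's colitis	inflammation	6
Ulcerative colitis	inflammation	4
Atrophic gastritis	inflammation	4
Proliferative diabetic retinopathy	inflammation	6
Old sepsis induced multiple organ failure	inflammation	6
Rheumatoid arthritis	inflammation	4
Osteoarthritis	inflammation	4
Intrahepatic cancer	cancer	6
Aortic occlusive disease	inflammation	3
Atherosclerosis	inflammation	3
Oxidized LDL	inflammation	3
Crohn's ileitis	inflammation	3
HP-infection with corpus-predominant atrophic gastritis	inflammation	2
Alzheimer's disease	inflammation	3
Old (macular retina)	inflammation	2
Homozygous familial hypercholesterolemia	inflammation	2
Psoriasis	inflammation	2
Asthma	inflammation	1
Systemic lupus erythematosus	inflammation	0
Diabetic kidney disease	inflammation	0
Type 1 diabetes	inflammation	0
Metabolic syndrome	inflammation	0
Homocysteine (100 umol/L)	inflammation	0
Pancreatic tumors	cancer	0
Prostate cancer	cancer	0
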