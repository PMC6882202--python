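disease	annual_cases	entity_name
BLCA	69300	Bladder Urothelial Carcinoma
BRCA	204800	Invasive Breast Carcinoma
CESC	14000	Cervical Squamous Cell Carcinoma
COAD	154840	Colon Adenocarcinoma
ESCA	4750	Esophageal Adenocarcinoma
GBM	3204	Glioblastoma Multiforme
HNSC	58000	Head & Neck Squamous Cell Carcinoma
KIRC	57600	Renal Clear Cell Carcinoma
KIRP	8064	Papilliary Renal Cell Carcinoma
LAML	13500	Acute Myeloid Leukemia
LIHC	29700	Hepatocellular Carcinoma
LUSC	66000	Lung Squamous Cell Carcinoma
OV	16800	Serous Ovarian Cancer
PRAD	260000	Prostate Adenocarcinoma
SKCM	75000	Melanoma
STAD	25000	Stomach Adenocarcinoma
THCA	46400	Thyroid Cancer
UCEC	55000	Endometrial Carcinoma
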