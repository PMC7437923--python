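concept	raw_indication	indication_id	drugs
Prostate Carcinoma	Advanced Prostate Carcinoma	DBCOND0070333	Cyproterone acetate;Esterified estrogens
Prostate Carcinoma	Advanced carcinoma of the prostate	DBCOND0020265	Goserelin
Acne Vulgaris	Severe Acne	DBCOND0077433	Cyproterone acetate;Doxycycline;Tetracycline
Acne Vulgaris	Acne	DBCOND0019842	Aloe Vera Leaf;Benzoyl peroxide;Chloramphenicol;Clioquinol;Glycolic acid;Linoleic acid;Octasulfur;Salicylic acid;Silver;Spironolactone
Acne Vulgaris	Moderate Acne vulgaris	DBCOND0022329	Ethinylestradiol;Minocycline;Norgestimate;Tazarotene
Dementia, Vascular	Mild Vascular Dementia	DBCOND0022662	Memantine
Dementia, Vascular	Dementia, Vascular	DBCOND0029264	Donepezil
Dementia, Vascular	Dementias	DBCOND0060453	Galantamine;Trazodone;Trifluoperazine
Idiopathic Pulmonary Fibrosis	Idiopathic Pulmonary Fibrosis (IPF)	DBCOND0031843	Nintedanib;Prednisolone
Idiopathic Pulmonary Fibrosis	Mild Idiopathic Pulmonary Fibrosis	DBCOND0093824	Pirfenidone
Paget Disease	Paget’s Disease	DBCOND0038793	Alendronic acid;Pamidronic acid;Risedronic acid;Zoledronic acid
Paget Disease	Paget’s Disease of Bone	DBCOND0030189	Etidronic acid
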