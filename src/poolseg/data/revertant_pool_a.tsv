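chromosome_position	dna_change	annotation	gene	description	frequency
chrXVI_65946	delACTT	Frameshift at T222	CLN2 (YPL256C)	G1 cyclin involved in regulation of the cell cycle	1.00
chrVI_218888	A > G	K407E	SMC2 (YFR031C)	Subunit of the condensin complex	1.00
chrIII_297908	G > C	S233T	GIT1 (YCR098C)	Plasma membrane permease	0.72
chrXIV_90717	G > C	V139L	CAF40 (YNL288W)	Component of the CCR4-NOT transcriptional complex	0.66
chrII_98352	G > C	L588F	SEF1 (YBL066C)	Putative transcription factor	0.49
chrVIII_484285	delT	Y87fs	PTH1 (YHR189W)	One of 2 mitochondrially localized peptidyl-tRNA hydrolases	0.47
chrXVI_252349	A > T	E654D	AIM44 (YPL158C)	Regulator of Cdc42p and Rho1p	0.47
chrIV_178744	G > T	W137C	MSH5 (YDL154W)	Protein of the MutS family	0.37
chrIV_322263	C > T	T13I	RPL31A (YDL075W)	Ribosomal 60S subunit protein L31A	0.25
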