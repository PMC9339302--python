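chromosome_position	dna_change	annotation	gene	description	frequency
chrXVI_65946	delACTT	Frameshift at T222	CLN2 (YPL256C)	G1 cyclin involved in regulation of the cell cycle	1.00
chrIV_322263	C > T	T13I	RPL31A (YDL075W)	Ribosomal 60S subunit protein L31A	1.00
chrIV_1193539	T > C	I449T	EAF1 (YDR359C)	Component of the NuA4 histone acetyltransferase complex	0.43
chrXVI_133275	C > G	A78G	FLC1 (YPL221W)	Flavin adenine dinucleotide transporter	0.31
chrV_191025	C > T	A255V	AFG3 (YER017C)	Mitochondrial inner membrane m-AAA protease component	0.27
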