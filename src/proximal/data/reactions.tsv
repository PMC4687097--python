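id	phase	enzymes	reactant	product	description
R01	I	1A2;2B6;2C9	antipyrine	hydroxymethylantipyrine	hydroxylation of the pyrazolone ring methyl
R02	I	1A1;1A2;1B1;3A4	bisphenol_a	bpa_hydroxy	aromatic hydroxylation ortho to the phenol
R03	I	1A2;2D6;2E1	bisphenol_a	bpa_dienone	phenolic hydroxyl to quinone-like carbonyl
R04	I	2E1	bisphenol_a	bpa_epoxide	arene epoxidation
R05	II	UGT	bisphenol_a	bpa_glucuronide	phenolic O-glucuronidation
R06	II	SULT	bisphenol_a	bpa_sulfate	phenolic O-sulfation
R07	I	2E1;1A2;3A4	acetaminophen	napqi	oxidation to the quinone imine
R08	II	UGT	acetaminophen	acetaminophen_glucuronide	phenolic O-glucuronidation
R09	II	SULT	acetaminophen	acetaminophen_sulfate	phenolic O-sulfation
R10	I	3A4;2D6	dimethylaniline	n_methylaniline	N-demethylation
R11	II	COMT	catechol	guaiacol	catechol O-methylation
R12	II	GST	benzene_oxide	benzene_oxide_gsh	epoxide ring-opening glutathione conjugation
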