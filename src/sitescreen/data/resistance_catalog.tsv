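target_gene	reference_species	reference_seq_id	position	wild_type_aa	resistant_aa	insecticide_class	numbering_note
DSC1	Drosophila melanogaster	Dmel_DSC1	1924	D	N	DDT	position in the DSC1 reference protein
Ryr	Plutella xylostella	Pxyl_Ryr	1338	E	D	diamide	diamondback-moth ryanodine receptor numbering
Ryr	Plutella xylostella	Pxyl_Ryr	4594	Q	L	diamide	diamondback-moth ryanodine receptor numbering
Ryr	Plutella xylostella	Pxyl_Ryr	4790	I	M	diamide	diamondback-moth ryanodine receptor numbering
Ryr	Plutella xylostella	Pxyl_Ryr	4946	G	E	diamide	diamondback-moth ryanodine receptor numbering
RDL	Drosophila melanogaster	Dmel_RDL	302	A	S	cyclodiene/fipronil	canonical RDL numbering
TAR1	Rhipicephalus microplus	Rmic_TAR1	8	T	P	formamidine	tick tyramine receptor 1 N-terminal numbering
TAR1	Rhipicephalus microplus	Rmic_TAR1	22	L	S	formamidine	tick tyramine receptor 1 N-terminal numbering
OctBAR2	Rhipicephalus microplus	Rmic_OctB2R	61	I	F	formamidine	tick octopamine beta-adrenergic-like receptor 2 numbering
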