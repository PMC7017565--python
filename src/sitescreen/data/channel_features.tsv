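feature_id	description	expected_motif	anchor	annotation_key	side	window	variant_motifs
selectivity_filter	sodium-channel-like pore selectivity filter (DEKA in true Nav; DEEA in SC1-type channels)	DEKA	absolute			0	DEEA
fast_inactivation	fast-inactivation gate of sodium-channel-like proteins	MFL	absolute			0	MFM
cys_loop	cys-loop disulfide signature of ligand-gated ion channel subunits	C-x(13)-C	absolute			0
pore_filter	anion/cation selectivity motif immediately preceding TM2	GEK	relative_to_annotation	TM2	before_start	10	KDR,PAR,ADR,SAR
dry_motif	GPCR activation motif at the end of TM3	DRY	relative_to_annotation	TM3	at_end	6
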