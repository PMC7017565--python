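# Post-translational-modification pattern catalog (PROSITE syntax).
# Columns: pattern_id <TAB> name <TAB> pattern
# Source: canonical PROSITE entries for the six classes scanned on
# phenolamine receptors; user-replaceable.
PS00001	N_GLYCOSYLATION	N-{P}-[ST]-{P}
PS00004	CAMP_PHOSPHO_SITE	[RK](2)-x-[ST]
PS00005	PKC_PHOSPHO_SITE	[ST]-x-[RK]
PS00006	CK2_PHOSPHO_SITE	[ST]-x(2)-[DE]
PS00008	MYRISTYL	G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}
PS00009	AMIDATION	x-G-[RK]-[RK]
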