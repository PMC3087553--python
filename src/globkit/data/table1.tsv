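# Amphioxus (B. floridae) globin gene catalog, transcribed from the published
# gene overview table. Scaffold IDs named in the text are real (39, 132, 89,
# 245); entries scaffold_u* are placeholders for scaffolds the text does not
# name. BflGb8's EST columns are blank in the source table with ambiguous
# adjacent formatting; this fixture records BflGb8 with zero ESTs.
gene_id	scaffold_id	alt_haplotype_id	haplotype_identity_pct	haplotype_similarity_pct	est_accessions	cds_accession	cds_coverage
BflGb1	scaffold_39	BRAFLDRAFT_92353	98.5	99.5		FN773089	complete
BflGb2	scaffold_39	BRAFLDRAFT_92354	95.9	97.3		FN773090	complete
BflGb3	scaffold_u3	BRAFLDRAFT_72350	99.4	100.0		FN773091	partial
BflGb4	scaffold_245	BRAFLDRAFT_84888	97.9	98.9		FN773092	complete
BflGb5	scaffold_132	BRAFLDRAFT_110609	97.8	98.9	BW852078	FN773093	complete
BflGb6	scaffold_89	BRAFLDRAFT_96513	100.0	100.0		FN773094	partial
BflGb7	scaffold_u7				BW695259;BW701618;BW702763;BW704772	FN773095	complete
BflGb8	scaffold_39	BRAFLDRAFT_92377	97.6	99.4		FN773096	partial
BflGb9	scaffold_132				BW696096;BW700672	FN773097	complete
BflGb10	scaffold_u10	BRAFLDRAFT_132915	97.2	98.6	BW717063;BW695770;BW698433	FN773098	complete
BflGb11	scaffold_u11	BRAFLDRAFT_133418	98.6	99.3	BW709730;BW700901;BW706678;BW695940;BW720248;BW721930;BW709489;BW717166;BW693523;BW692993;BW710133;BW699215;BW698534;BW709034;BW701461;BW703104;AU234573	FN773099	complete
BflGb12	scaffold_89					FN773100	partial
BflGb13	scaffold_u13	BRAFLDRAFT_111239	98.9	100.0		FN773101	complete
BflGb14	scaffold_u14					FN773102	complete
BflGb15	scaffold_39	BRAFLDRAFT_90367	98.6	99.3		FN773103	complete
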