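# Micro-synteny map of the B. floridae scaffold-245 region around BflGb4.
# POMT2 and GSTZ1 adjacency is stated in the source text; flanking filler
# genes (famX*) are synthetic placeholders to give the window realistic
# occupancy. No TMEM63C ortholog is present on this scaffold (stated).
region	position_index	gene_label	family_id	strand
scaffold_245	0	bfl_g1	famX1	+
scaffold_245	1	bfl_g2	famX2	-
scaffold_245	2	BflGb4	NGB_family	+
scaffold_245	3	bfl_pomt2	POMT2	+
scaffold_245	4	bfl_gstz1	GSTZ1	-
scaffold_245	5	bfl_g5	famX3	+
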