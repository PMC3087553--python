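# Micro-synteny map of human 14q24.3 around NGB: NGB lies between POMT2
# and TMEM63C, with POMT2 and GSTZ1 on the distal (telomeric) side, as
# stated in the source text. famY* fillers are synthetic placeholders.
region	position_index	gene_label	family_id	strand
HSA14q24.3	0	hsa_g1	famY1	+
HSA14q24.3	1	TMEM63C	TMEM63C	+
HSA14q24.3	2	NGB	NGB_family	+
HSA14q24.3	3	POMT2	POMT2	-
HSA14q24.3	4	GSTZ1	GSTZ1	+
HSA14q24.3	5	hsa_g6	famY2	-
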