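# Canonical globin-fold segment annotation for a 155-residue model globin.
# Transcription of helix extents is approximate (segment boundaries follow
# the standard A–H fold with inter-helix segments); used by examples and
# tests, supplied as input — never derived from structure by this package.
segment	start	end
NA	1	5
A	6	21
B	22	37
C	38	44
CD	45	52
D	53	59
E	60	79
EF	80	87
F	88	97
FG	98	102
G	103	121
GH	122	126
H	127	147
HC	148	155
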