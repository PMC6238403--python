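# Family counts per clade from the published mollusc LTR-retrotransposon
# census: families defined from the nine complete genomes (with structural
# copy numbers in the source's brackets) and families from database mining
# across 46 further species. Rows follow the printed order. Bracketed copy
# numbers are stored as printed but are typographically unreliable in the
# source (e.g. the CoMol bracket conflicts with the stated 11 copies) and
# are excluded from arithmetic verification.
superfamily	clade	families_genome	copies_genome_bracket	families_database
Copia	GalEa	15	183	57
Copia	Hydra	6	125	37
Copia	CoMol	1	185	3
BELPao	Sparrow	70	425	60
BELPao	Sinbad	24	241	32
BELPao	Surcouf	8	28	15
BELPao	Tas	16	91	76
BELPao	Suzu	12	127	19
BELPao	Flow	2	9	12
BELPao	Dan	0	0	5
Gypsy	C-clade	111	3021	114
Gypsy	MolGy1	73	539	66
Gypsy	AB-clade	32	3031	43
Gypsy	MolGy2	149	2302	83
Gypsy	MolGy3	38	264	20
Gypsy	MolGy4	9	916	17
Gypsy	MolGy5	9	5111	17
Gypsy	CsRN1	24	3115	31
Gypsy	MolGy6	41	302	20
Gypsy	MolGy12	9	284	16
Gypsy	Cigr-1	12	1476	3
Gypsy	MolGy7	3	85	7
Gypsy	MolGy9	0	0	10
Gypsy	MolGy13	8	31	0
Gypsy	MolGy8	2	780	5
Gypsy	MolGy10	3	43	4
Gypsy	MolGy11	5	53	2
Gypsy	MolGy16	7	1029	1
Gypsy	MolGy14	3	32	2
Gypsy	MolGy15	0	0	4
Gypsy	Tor2	0	0	4
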