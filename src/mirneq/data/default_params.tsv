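# mirneq default nearest-neighbor parameter table (Turner-style, 37 C)
# columns: kind<TAB>key<TAB>value_kcal_mol
stack	AA/UU	-0.93
stack	AC/UG	-2.24
stack	AG/UC	-2.08
stack	AG/UU	-0.55
stack	AU/UA	-1.10
stack	AU/UG	-1.36
stack	CA/GU	-2.11
stack	CC/GG	-3.26
stack	CG/GC	-2.36
stack	CG/GU	-1.41
stack	CU/GA	-2.08
stack	CU/GG	-2.11
stack	GA/CU	-2.35
stack	GA/UU	-1.00
stack	GC/CG	-3.42
stack	GC/UG	-2.51
stack	GG/CC	-3.26
stack	GG/CU	-1.53
stack	GG/UC	-2.11
stack	GG/UU	-0.50
stack	GU/CA	-2.24
stack	GU/CG	-2.51
stack	GU/UA	-1.36
stack	GU/UG	0.47
stack	UA/AU	-1.33
stack	UA/GU	-1.27
stack	UC/AG	-2.35
stack	UC/GG	-1.53
stack	UG/AC	-2.11
stack	UG/AU	-1.27
stack	UG/GC	-1.41
stack	UG/GU	-0.60
stack	UU/AA	-0.93
stack	UU/AG	-1.00
stack	UU/GA	-0.55
stack	UU/GG	-0.50
hairpin	3	5.70
hairpin	4	5.60
hairpin	5	5.60
hairpin	6	5.40
hairpin	7	5.90
hairpin	8	5.60
hairpin	9	6.40
hairpin	10	6.51
hairpin	11	6.62
hairpin	12	6.71
hairpin	13	6.80
hairpin	14	6.88
hairpin	15	6.95
hairpin	16	7.02
hairpin	17	7.09
hairpin	18	7.15
hairpin	19	7.21
hairpin	20	7.26
hairpin	21	7.31
hairpin	22	7.36
hairpin	23	7.41
hairpin	24	7.46
hairpin	25	7.50
hairpin	26	7.54
hairpin	27	7.58
hairpin	28	7.62
hairpin	29	7.66
hairpin	30	7.70
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.57
bulge	8	4.71
bulge	9	4.84
bulge	10	4.95
bulge	11	5.05
bulge	12	5.15
bulge	13	5.23
bulge	14	5.31
bulge	15	5.39
bulge	16	5.46
bulge	17	5.52
bulge	18	5.58
bulge	19	5.64
bulge	20	5.70
bulge	21	5.75
bulge	22	5.80
bulge	23	5.85
bulge	24	5.90
bulge	25	5.94
bulge	26	5.98
bulge	27	6.02
bulge	28	6.06
bulge	29	6.10
bulge	30	6.14
internal	1	3.50
internal	2	3.50
internal	3	3.60
internal	4	3.90
internal	5	4.10
internal	6	4.30
internal	7	4.47
internal	8	4.61
internal	9	4.74
internal	10	4.85
internal	11	4.95
internal	12	5.05
internal	13	5.13
internal	14	5.21
internal	15	5.29
internal	16	5.36
internal	17	5.42
internal	18	5.48
internal	19	5.54
internal	20	5.60
internal	21	5.65
internal	22	5.70
internal	23	5.75
internal	24	5.80
internal	25	5.84
internal	26	5.88
internal	27	5.92
internal	28	5.96
internal	29	6.00
internal	30	6.04
duplex_initiation	-	4.09
terminal_au	-	0.45
multiloop_offset	-	3.40
multiloop_branch	-	0.40
multiloop_unpaired	-	0.00
loop_extrapolation_c	-	1.0785
temperature	-	310.15
gas_constant	-	0.001987
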