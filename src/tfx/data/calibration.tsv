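toxin_id	original_pos	expected_column	status	note
erabutoxin_a	7	7	hard	loop I Gln
erabutoxin_a	8	8	hard	loop I Ser
erabutoxin_a	10	10	hard	loop I Gln
erabutoxin_a	11	11	hard	loop I flanking Pro
erabutoxin_a	27	27	hard	loop II core Lys
erabutoxin_a	29	29	hard	loop II core Trp
erabutoxin_a	31	31	hard	loop II Asp
erabutoxin_a	32	36	hard	loop II Phe
erabutoxin_a	33	37	hard	loop II core Arg
erabutoxin_a	34	38	hard	loop II Gly
erabutoxin_a	35	39	hard	loop II Thr
erabutoxin_a	36	40	hard	loop II Ile
erabutoxin_a	38	42	hard	loop II Glu
erabutoxin_a	44	50	hard	loop III flanking Pro
erabutoxin_a	47	53	hard	loop III core Lys
erabutoxin_a	48	54	hard	loop III flanking Pro
alpha-cobratoxin	23	27	hard	loop II Lys
alpha-cobratoxin	25	29	hard	loop II Trp
alpha-cobratoxin	26	30	hard	fifth-disulfide Cys
alpha-cobratoxin	27	31	hard	loop II Asp
alpha-cobratoxin	28	32	hard	loop II Ala
alpha-cobratoxin	29	33	hard	loop II Phe
alpha-cobratoxin	30	34	hard	fifth-disulfide Cys
alpha-cobratoxin	33	37	hard	loop II core Arg
alpha-cobratoxin	35	39	hard	loop II Lys
alpha-cobratoxin	36	40	hard	loop II Arg
alpha-cobratoxin	49	53	hard	loop III Lys
alpha-cobratoxin	65	70	hard	C-tail Phe
alpha-bungarotoxin	28	32	hard	loop II Ser isoform position
alpha-bungarotoxin	29	33	hard	loop II His
alpha-bungarotoxin	36	40	hard	loop II Val
kappa-bungarotoxin	48	52	hard	interface Phe
kappa-bungarotoxin	49	53	hard	loop III Arg
candoxin	27	29	hard	loop II Glu
candoxin	29	31	hard	loop II Trp
candoxin	31	33	hard	loop II Glu
candoxin	33	39	hard	loop II Arg
candoxin	36	42	hard	loop II Arg
candoxin	38	44	hard	loop II Glu
candoxin	47	55	hard	loop III Ser (Lys position)
WTX	27	29	hard	loop II Lys
WTX	29	31	hard	loop II His
WTX	31	33	hard	loop II Arg
WTX	32	37	hard	loop II Arg
WTX	36	41	hard	loop II Trp
WTX	37	42	hard	mAChR determinant Arg
WTX	47	55	hard	loop III Lys
Oh9-1	7	7	hard	loop I His
Oh9-1	22	27	hard	loop II Lys
Oh9-1	23	28	hard	loop II Thr
Oh9-1	24	29	hard	loop II Thr
Oh9-1	25	30	hard	loop II Met
Oh9-1	26	31	hard	loop II Phe
Oh9-1	27	32	hard	loop II Phe
Oh9-1	28	33	hard	loop II Pro
Oh9-1	30	38	hard	loop II His
Oh9-1	31	39	hard	loop II Pro
Oh9-1	45	53	hard	loop III Lys
Oh9-1	46	54	hard	loop III Tyr
fulditoxin	17	21	hard	Glu of group 1a
fulditoxin	26	30	hard	dimer-interface Gly
fulditoxin	35	42	hard	dimer-interface Ile
fulditoxin	37	44	hard	dimer-interface Thr
TIII_1A	30	37	hard	class 1a Gly
denmotoxin	40	55	soft	kink Pro; printed as both 55 and 56
denmotoxin	40	56	soft	kink Pro; printed as both 55 and 56
TIII_2	59	71	soft	tail Tyr; Type III figure frame offset
kappa-bungarotoxin	56	60	soft	interface Leu printed on the Cys#6 column
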