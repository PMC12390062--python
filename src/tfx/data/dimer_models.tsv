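model	column	residue	confidence
haditoxin	7	Q	curated
haditoxin	8	S	curated
haditoxin	23	F	curated
haditoxin	42	E	curated
haditoxin	54	L	curated
kappa	27	K	curated
kappa	37	R	curated
kappa	52	F	curated
kappa	53	R	curated
kappa	58	L	curated
sigma	26	I	figure-derived,low
sigma	29	L	figure-derived,low
sigma	31	F	figure-derived,low
sigma	33	H	figure-derived,low
sigma	34	I	figure-derived,low
sigma	44	T	figure-derived,low
dpp2d	33	W	curated
dpp2d	58	E	curated
dpp2d	59	K	curated
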