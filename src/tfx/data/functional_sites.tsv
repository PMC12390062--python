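model	column	residue	role
erabutoxin_a	7	Q	variant
erabutoxin_a	8	S	variant
erabutoxin_a	10	Q	variant
erabutoxin_a	27	K	core
erabutoxin_a	29	W	core
erabutoxin_a	31	D	variant
erabutoxin_a	36	F	variant
erabutoxin_a	37	R	core
erabutoxin_a	42	E	variant
erabutoxin_a	53	K	core
alpha-cobratoxin/torpedo	27	K	core
alpha-cobratoxin/torpedo	29	W	core
alpha-cobratoxin/torpedo	31	D	core
alpha-cobratoxin/torpedo	33	F	variant
alpha-cobratoxin/torpedo	37	R	core
alpha-cobratoxin/torpedo	40	R	variant
alpha-cobratoxin/torpedo	53	K	core
alpha-cobratoxin/torpedo	70	F	variant
alpha-cobratoxin/alpha7	29	W	core
alpha-cobratoxin/alpha7	31	D	core
alpha-cobratoxin/alpha7	32	A	variant
alpha-cobratoxin/alpha7	33	F	variant
alpha-cobratoxin/alpha7	37	R	core
alpha-cobratoxin/alpha7	39	K	variant
alpha-cobratoxin/alpha7	40	R	variant
alpha-cobratoxin/alpha7	70	F	variant
WTX	29	K	variant
WTX	31	H	variant
WTX	33	R	core
WTX	37	R	core
WTX	41	W	variant
WTX	42	R	variant
WTX	55	K	variant
Oh9-1/muscle	7	H	core
Oh9-1/muscle	27	K	core
Oh9-1/muscle	28	T	variant
Oh9-1/muscle	29	T	variant
Oh9-1/muscle	30	M	core
Oh9-1/muscle	31	F	variant
Oh9-1/muscle	32	F	core
Oh9-1/muscle	38	H	core
Oh9-1/muscle	53	K	core
Oh9-1/alpha3beta2	7	H	core
Oh9-1/alpha3beta2	27	K	core
Oh9-1/alpha3beta2	30	M	core
Oh9-1/alpha3beta2	32	F	core
Oh9-1/alpha3beta2	38	H	core
Oh9-1/alpha3beta2	53	K	core
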