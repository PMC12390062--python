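"""Published residue-number / homology-number calibration pairs.

Each hard pair (toxin, original position, expected frame column) must be
reproduced exactly by ``align_to_frame``.  Soft pairs are recorded for
completeness but excluded from the hard set: the literature prints them
inconsistently (the denmotoxin kink proline appears with two different
homology numbers) or they belong to a per-family figure frame that is not
globally consistent with the short/long-chain columns (the Type III tail
tyrosine).
"""

# (toxin_id in the anchor file, original position, expected column, note)
CALIBRATION_PAIRS = [
    # -- erabutoxin a (Type I reference) --
    ("erabutoxin_a", 7, 7, "loop I Gln"),
    ("erabutoxin_a", 8, 8, "loop I Ser"),
    ("erabutoxin_a", 10, 10, "loop I Gln"),
    ("erabutoxin_a", 11, 11, "loop I flanking Pro"),
    ("erabutoxin_a", 27, 27, "loop II core Lys"),
    ("erabutoxin_a", 29, 29, "loop II core Trp"),
    ("erabutoxin_a", 31, 31, "loop II Asp"),
    ("erabutoxin_a", 32, 36, "loop II Phe"),
    ("erabutoxin_a", 33, 37, "loop II core Arg"),
    ("erabutoxin_a", 34, 38, "loop II Gly"),
    ("erabutoxin_a", 35, 39, "loop II Thr"),
    ("erabutoxin_a", 36, 40, "loop II Ile"),
    ("erabutoxin_a", 38, 42, "loop II Glu"),
    ("erabutoxin_a", 44, 50, "loop III flanking Pro"),
    ("erabutoxin_a", 47, 53, "loop III core Lys"),
    ("erabutoxin_a", 48, 54, "loop III flanking Pro"),
    # -- alpha-cobratoxin (Type II reference) --
    ("alpha-cobratoxin", 23, 27, "loop II Lys"),
    ("alpha-cobratoxin", 25, 29, "loop II Trp"),
    ("alpha-cobratoxin", 26, 30, "fifth-disulfide Cys"),
    ("alpha-cobratoxin", 27, 31, "loop II Asp"),
    ("alpha-cobratoxin", 28, 32, "loop II Ala"),
    ("alpha-cobratoxin", 29, 33, "loop II Phe"),
    ("alpha-cobratoxin", 30, 34, "fifth-disulfide Cys"),
    ("alpha-cobratoxin", 33, 37, "loop II core Arg"),
    ("alpha-cobratoxin", 35, 39, "loop II Lys"),
    ("alpha-cobratoxin", 36, 40, "loop II Arg"),
    ("alpha-cobratoxin", 49, 53, "loop III Lys"),
    ("alpha-cobratoxin", 65, 70, "C-tail Phe"),
    # -- alpha-bungarotoxin (same long-chain geometry) --
    ("alpha-bungarotoxin", 28, 32, "loop II Ser isoform position"),
    ("alpha-bungarotoxin", 29, 33, "loop II His"),
    ("alpha-bungarotoxin", 36, 40, "loop II Val"),
    # -- kappa-bungarotoxin (positional pairs of the dimer interface) --
    ("kappa-bungarotoxin", 48, 52, "interface Phe"),
    ("kappa-bungarotoxin", 49, 53, "loop III Arg"),
    # -- candoxin (non-conventional class 1) --
    ("candoxin", 27, 29, "loop II Glu"),
    ("candoxin", 29, 31, "loop II Trp"),
    ("candoxin", 31, 33, "loop II Glu"),
    ("candoxin", 33, 39, "loop II Arg"),
    ("candoxin", 36, 42, "loop II Arg"),
    ("candoxin", 38, 44, "loop II Glu"),
    ("candoxin", 47, 55, "loop III Ser (Lys position)"),
    # -- WTX (non-conventional class 3) --
    ("WTX", 27, 29, "loop II Lys"),
    ("WTX", 29, 31, "loop II His"),
    ("WTX", 31, 33, "loop II Arg"),
    ("WTX", 32, 37, "loop II Arg"),
    ("WTX", 36, 41, "loop II Trp"),
    ("WTX", 37, 42, "mAChR determinant Arg"),
    ("WTX", 47, 55, "loop III Lys"),
    # -- Oh9-1 (omega reference) --
    ("Oh9-1", 7, 7, "loop I His"),
    ("Oh9-1", 22, 27, "loop II Lys"),
    ("Oh9-1", 23, 28, "loop II Thr"),
    ("Oh9-1", 24, 29, "loop II Thr"),
    ("Oh9-1", 25, 30, "loop II Met"),
    ("Oh9-1", 26, 31, "loop II Phe"),
    ("Oh9-1", 27, 32, "loop II Phe"),
    ("Oh9-1", 28, 33, "loop II Pro"),
    ("Oh9-1", 30, 38, "loop II His"),
    ("Oh9-1", 31, 39, "loop II Pro"),
    ("Oh9-1", 45, 53, "loop III Lys"),
    ("Oh9-1", 46, 54, "loop III Tyr"),
    # -- fulditoxin (sigma reference) --
    ("fulditoxin", 17, 21, "Glu of group 1a"),
    ("fulditoxin", 26, 30, "dimer-interface Gly"),
    ("fulditoxin", 35, 42, "dimer-interface Ile"),
    ("fulditoxin", 37, 44, "dimer-interface Thr"),
    # -- Type III exemplar (class 1a) --
    ("TIII_1A", 30, 37, "class 1a Gly"),
]

SOFT_PAIRS = [
    ("denmotoxin", 40, 55, "kink Pro; printed as both 55 and 56"),
    ("denmotoxin", 40, 56, "kink Pro; printed as both 55 and 56"),
    ("TIII_2", 59, 71, "tail Tyr; Type III figure frame offset"),
    ("kappa-bungarotoxin", 56, 60, "interface Leu printed on the Cys#6 column"),
]
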