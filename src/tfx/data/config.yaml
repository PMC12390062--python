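# Frozen alignment defaults (version 1).  Substitution scores are BLOSUM62;
# a Cys placed in one of the eight anchor columns earns anchor_bonus, which
# dominates any gap rearrangement and makes anchor crossing impossible.
# Gap opening is cheaper inside loop regions than in the disulfide core.
version: 1
anchor_bonus: 40
gap_open_core: -11
gap_open_loop: -7
gap_extend: -1
# number of screened per-class profiles refined by full dynamic programming
dp_candidates: 6
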