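# tfx — three-finger neurotoxin numbering and classification

Snake-venom three-finger toxins (3FTxs) are small, disulfide-stabilised
proteins whose neurotoxic members block nicotinic acetylcholine receptors
(nAChRs).  The family divides into short-chain (Type I) and long-chain
(Type II) α-neurotoxins plus several younger families — Type III,
non-conventional (fifth disulfide in loop I), Ω-, Σ- and colubrid
neurotoxins — and, within each, into a fine taxonomy of classes, groups and
subgroups defined by substitutions at functional-site residues, flanking
prolines, loop lengths, C-terminal tails and precursor processing.  `tfx`
turns that taxonomy into a reusable classifier for protein sequences.

`tfx` is aimed at venom researchers annotating transcriptome/proteome
output: it assigns any mature 3FTx (or colubrid precursor) to one of 158
subgroups and reports the evidence for the call.

## The model

Two components carry the science:

1. **A Cys-anchored homology frame.**  All 3FTx families share eight
   conserved cysteines.  `tfx` fixes them at frame columns
   3, 17, 24, 45, 47, 60, 61 and 66 of a single cross-family coordinate
   system and aligns each input to per-class column profiles by global
   affine-gap alignment with a Cys–Cys anchor bonus that makes anchor
   crossing impossible.  A residue's homology number is its column; output
   uses the dual notation *n(m)* — original position *n*, homology number
   *m*, with *(m)* omitted when the two agree.  Columns match the numbering
   used in the α-neurotoxin mutagenesis literature (the loop II arginine of
   erabutoxin a is Arg33(37); the tail phenylalanine of α-cobratoxin is
   Phe65(70)).  Colubrid N-terminal extensions occupy columns ≤ 0.

2. **A 158-leaf rule registry.**  Each subgroup is a conjunction of atomic
   clauses over extracted features — `pos(36)=H`, `ctail=9`, `ncys=10`,
   `fifth_ss_loop=1`, `proflanks={11,50,54}`, `motif(CYTLY,loop2)`,
   `procsite(XaaGln)`, `dimer_model(kappa,0.8)` … — evaluated with
   three-valued logic (an `X` at a decisive column is *unknown*, never a
   pass).  Family totals are Type I 36, Type II 56, Type III 3,
   non-conventional 20, Ω 5, Σ 7, colubrid 31.  A uniquely satisfied leaf
   is an `exact` call; several are `ambiguous`; none falls back to the
   `nearest` leaf by violated-clause count.

A seeded generator (`tfx.synthdata`) produces subgroup-faithful synthetic
fixtures for every leaf, which makes the whole classifier testable without
any sequence downloads.  All shipped reference sequences are synthetic
calibrated stand-ins, not real venom records.

## Worked example

Generate a short-chain (erabutoxin-like) fixture and classify it:

```sh
$ tfx generate --leaf TypeI/1/1a --seed 7 -o era.fasta
$ tfx classify era.fasta
id                  family  class  group  subgroup  confidence  satisfied  violated  ...
syn|TypeI/1/1a|7.0  TypeI   1      1a     -         exact       21         0         ...
```

The fixture satisfies all 21 clauses of the `TypeI/1/1a` leaf (erabutoxin
group) and no other, so the call is `exact`.  The site-residue column shows
the functional site the rule saw: `7:Q;8:S;10:Q;27:K;29:W;31:D;36:F;37:R;
40:I;42:E;53:K` — the ten loop I–III residues of the classical short-chain
site, each at its homology column.

`tfx profile` prints the dual numbering and the loop architecture:

```sh
$ tfx profile era.fasta
>syn|TypeI/1/1a|7.0  family=TypeI profile=TI_STD score=536.0 anchors=8/8
  numbering: 1 2 ... 31 32(36) 33(37) 34(38) ... 47(53) 48(54) ... 62(68)
  loops: I=13 II=16 III=10 tail=2 ncys=8 fifth_ss=none
```

Position 33 maps to column 37 and position 47 to column 53 — the loop II
arginine and loop III lysine of the common functional core — and the tail
has the two residues typical of short-chain toxins.  `tfx registry stats`
prints the per-family class/group/subgroup table (36/56/3/20/5/7/31,
total 158).

Colubrid precursors are handled end to end: `tfx classify --form
precursor_signal_removed` detects the propeptide processing site
(Xaa-Gln, mono-/di-/tri-/tetra-/pentabasic), derives the mature chain and
reports the N-terminal extension and pyroglutamate candidate.

## Layout

```
src/tfx/            the library (records, layouts, frame, features,
                    precursor, criteria, taxonomy, conservation,
                    synthdata, cli)
src/tfx/data/       shipped artefacts: anchor alignment, calibration
                    table, registry, site/dimer tables, config
scripts/            acceptance.py and the data-file renderer
docs/methods.md     model assumptions, parameters and limitations
```
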