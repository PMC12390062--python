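# Methods

## The homology frame

The classifier's coordinate system is a single global frame of columns
−16…92.  The eight cysteines conserved across all three-finger toxin
families are anchors at columns 3, 17, 24, 45, 47, 60, 61, 66; every other
column is ordinary.  Canonical columns 1–92 reproduce the homology numbers
used in the α-neurotoxin mutagenesis literature for Type I/II positions
(erabutoxin a Arg33 → 37, Lys47 → 53; α-cobratoxin Lys49 → 53,
Phe65 → 70); colubrid N-terminal extensions take columns ≤ 0 with 0 the
residue immediately before the canonical start.  A shipped calibration
table (`data/calibration.tsv`) freezes 64 hard (toxin, original position,
column) pairs across seven families; `align_to_frame` must reproduce all
of them, and the acceptance suite checks it does.

One deliberate modelling choice: the literature's per-family figure
alignments are *not* mutually consistent as one alignment (the loop III
lysine is column 53 in Type I and Ω but 55 in non-conventional toxins; the
Type III tail tyrosine is printed at 71 where the global frame gives 73).
The frame therefore hosts family- and class-specific gap layouts: each
family places its residues on its own published columns, and homologous
residues of two families need not share a column.  Pairs that are
internally inconsistent in print (the denmotoxin kink proline, printed
with two different numbers; the Type III tail tyrosine; the
κ-neurotoxin interface leucine printed on the Cys#6 column) are recorded
in the calibration file as `soft` and excluded from the hard set.

### Alignment

Inputs are aligned to per-class column profiles (one exemplar per distinct
class geometry, 21 in all) by global dynamic programming:

* substitution scores: BLOSUM62 against consensus columns; *variable*
  profile columns (lowercase in `data/anchors.afa`) score a flat +1 for
  any residue, so the register is pinned by the consensus columns and the
  Cys anchors alone.  Tail columns are always variable — the tail has no
  downstream anchor, and a consensus residue there would let a chance
  match pay for a register shift;
* anchor bonus +40 for a Cys placed in an anchor column (large enough
  that anchor crossing can never pay);
* affine gaps, opening −11 in the disulfide core and −7 inside loops and
  tails, extension −1; leading/trailing profile columns are free
  (extensions and tail truncations);
* ties prefer match over column deletion over insertion, i.e. leftmost
  gap placement; all parameters are frozen in `data/config.yaml`.

Every profile is first screened with an indel-free scan; the best six
candidates are refined by full dynamic programming (`dp_candidates` in the
config).  Score ties between profiles sharing a body go to the profile
closest in length.  A sequence that cannot put a Cys in every anchor
column is returned flagged `anchor_incomplete` (the colubrid class with
two missing conserved cysteines relies on this), with the unmatched
anchors listed.

Loop boundaries are defined by Cys ordinals — loop I strictly between
Cys#1 and #2, loop II between #3 and #4, loop III between #5 and #6, tail
after #8.  This places every published functional residue in its stated
loop for the short- and long-chain references, which is the criterion the
unit tests pin down; the literature never defines the boundaries formally.

## The registry

158 leaves (Type I 36, Type II 56, Type III 3, non-conventional 20, Ω 5,
Σ 7, colubrid 31) follow the running-text enumeration of the taxonomy,
which — unlike the summary table, whose subgroup column undercounts the
colubrids — sums to the printed per-family totals.  Ambiguities in the
source numbering are resolved once and documented in the criteria notes:
group "1j" is read as 1i, the duplicated Type II "via–b" label as
viiia–b, the Σ group 2d is merged to keep the printed total of 7, and the
Ω class/group sentence is read against the class descriptions (class 1
has four groups, class 2 one).

Predicates are conjunctions in a small DSL (`pos(C)=R`, `pos(C) in {...}`,
`pos(C)=del`, loop/tail lengths, `ncys`, `anchors`, `extra_cys_at`,
`fifth_ss_loop`, `proflanks={...}` with exact-set semantics, loop II
motifs, terminal flags, `nterm_ext`, `procsite`/`procmotif`,
`dimer_model(name,frac)`, `covalent`).  Every leaf pins its family's full
decision schema, so sibling leaves always differ in at least one atom and
generated fixtures satisfy exactly one leaf; disjunction exists only as a
value set inside an atom.  Evaluation is three-valued: an `X` at a
decisive column, a length undefined by a missing anchor, or absent
precursor information make a clause *unknown*, and a leaf with unknown
clauses can never be an `exact` call.

Family gating happens through the alignment itself (the best-scoring
profile fixes the family); leaves of that family are then ranked by
(satisfied clauses desc, specificity desc, path).  Ambiguity is surfaced,
never silently resolved.  Dimeric classes are classified per chain from
sequence features and reported as sequence-inferred; the covalent
α-cobratoxin dimers are sequence-identical to their monomeric siblings,
so those two leaves additionally key on a user-supplied `covalent_dimer`
record annotation.

### Feature conventions

* Extra cysteines: a pair strictly inside columns 5–15 is the loop I
  fifth disulfide; the pair at 30/34 is the long-chain loop II
  disulfide.  The free-thiol/disulfide status of other surplus cysteines
  is a parity-and-position heuristic and always labelled inferred — for
  the ten-Cys short-chain class the pairing is genuinely unresolved.
* Disulfide connectivity is assumed canonical (I–III, II–IV, V–VI,
  VII–VIII) for reporting only; it is never a classification predicate.
* A terminal Gly sets an **amidation candidate** flag, never an amidation
  claim (at least one Σ toxin carries terminal Gly unamidated); an
  N-terminal Gln sets a pyroglutamate candidate flag.
* Flanking prolines are evaluated only at columns 7, 11, 12 (loop I) and
  50, 54 (loop III), the positions the criteria use.
* Conservative-substitution groups: aromatic {F,W,Y,H}, positive {K,R},
  negative {D,E}, small {G,S,A}, hydrophobic {L,I,V,M,F,W} — His can
  replace Phe in stacking, Arg an aromatic via π-cation.
* The Σ dimer-interface column set is figure-derived and marked low
  confidence in `data/dimer_models.tsv`; the κ interface leucine is
  curated at column 58 because its printed number collides with an anchor
  column.

## Precursor processing

Colubrid toxins mature from precursors.  With the signal peptide already
removed (`form=precursor_signal_removed`), the propeptide window (first 25
residues, before the first cysteine — propeptides carry none) is scanned
for basic runs; the priority order pentabasic RRKKK > tetrabasic >
tribasic KKK > dibasic > monobasic > Xaa-Gln is total, and back-to-back
dibasic sites read as tetrabasic.  Cleavage is C-terminal to the basic
run and N-terminal to the Gln for Xaa-Gln sites; the mature start is
exposed so either convention can be overridden.  An Xaa-Gln call
additionally requires the Gln to start a plausible three-finger region
(≥ 8 downstream cysteines, the first within 11 residues).  The N-terminal
extension is measured after alignment as the number of residues preceding
canonical column 1 (elapid toxins give 0; colubrid classes 5–17).
Detection assumes a colubrid-style precursor; it is not meaningful for
elapid sequences, which should be supplied mature.

## The synthetic-data generator

Fixtures are built per leaf from the family scaffold on the leaf's column
layout: anchors and all predicate-constrained columns fixed, free
positions drawn from a fixed background alphabet by a seeded integer-state
generator.  The background excludes Cys, Trp and Pro so that cysteine
topology, motif content and flanking-proline calls cannot drift; extension
and propeptide filler additionally excludes basics and Gln so the
processing-site scan cannot be confounded.  Colubrid fixtures are emitted
as signal-less precursors with class-appropriate propeptides
(15-residue propeptides for the monomeric class 1 and the heterodimer
subunits, 7–8 residues for classes 2–6, per the published lengths).

What the fixtures emulate: correct class geometry (loop lengths within the
published ranges — short-chain 57–62 residues, long-chain 66–75, Ω/Type
III 57–58 — tail lengths, extensions), exact decision-column content, and
family-typical scaffold residues.  What they do not emulate: realistic
background composition, within-subgroup natural variation beyond the
mutation model, sequencing noise, or evolutionary correlation between
positions.  A passing round-trip therefore shows the classifier is
consistent and discriminating over the taxonomy's defining features; it
does not certify performance on noisy real-world transcripts, where
`nearest` calls with few violated clauses should be reviewed by eye.

`mutate` substitutes explicitly addressed columns/positions (constrained
positions only via explicit request) or free positions at a given rate,
records the edit list in metadata, and preserves the leaf label by
construction in rate mode.

## Problem sizes and numerics

The acceptance computations use one fixture per leaf over three seeds
(474 classifications), a 400-sequence cohort for conservation recovery at
a 0.85 canonical frequency (binomial 99% interval), 15 documented
subgroup pivots, and the 64-pair hard calibration table; together they
run in about a minute on one CPU.  Conservation denominators are the
non-gap occupancy of a column, so deletions never read as substitutions —
the published field-wide percentages use an unstated denominator and an
undeposited dataset, and are deliberately not reproduced.

## Known limitations

* The registry encodes one concrete residue tuple per subgroup where the
  source text lists several members with internal variation; borderline
  natural sequences may come back `nearest` rather than `exact`.
* Family assignment rides on profile alignment; a chimeric or heavily
  gapped sequence can gate into the wrong family and will then at best be
  `nearest` there.
* Quaternary structure is never observed, only inferred from sequence
  features or user annotation.
* Nucleotide input, signal-peptide prediction, phylogenetics, structure
  prediction and binding-affinity prediction are out of scope.
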