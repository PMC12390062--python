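"""Subgroup-faithful synthetic fixtures for closed-loop testing.

Each registry leaf has a deterministic template: the family scaffold on the
leaf's column layout with every predicate-constrained column fixed to a
satisfying residue.  Free positions are drawn from a fixed background
alphabet (no Cys, Trp or Pro, so cysteine topology, motif content and
flanking-proline calls cannot drift).  Colubrid leaves are emitted as
signal-less precursors carrying their propeptide.  Sequences are synthetic
and labelled as such; they are not real venom sequences.
"""

from __future__ import annotations

import random

from .criteria import LEAVES, LeafSpec, leaf_by_path
from .layouts import CYS_ANCHOR_COLS, FLANK_COLS
from .records import ToxinRecord
from .templates import BACKGROUND, SCAFFOLD, background_residue

#: residues used for unconstrained positions and substitutions
FREE_ALPHABET = BACKGROUND.replace("W", "")
#: extension/propeptide filler: additionally no basics or Gln, so the
#: processing-site scan cannot be confounded
NEUTRAL_ALPHABET = "ASTGNDELIV"

_NONFLANK_DEFAULT = {7: "T", 11: "S", 12: "T", 50: "A", 54: "S"}


class GenerationError(ValueError):
    """A leaf predicate cannot be satisfied by construction."""


def _first(v):
    if isinstance(v, tuple):
        return sorted(v)[0]
    return v


def constrained_overrides(leaf: LeafSpec) -> dict[int, str]:
    """Column -> residue map of every generator-fixed position of a leaf."""
    lay = leaf.layout
    cols = set(lay.cols)
    a = leaf.atoms
    over: dict[int, str] = {}
    # proline flanks: exact-set semantics
    if a.get("proflanks") is not None:
        want = set(a["proflanks"])
        for c in FLANK_COLS:
            if c not in cols:
                if c in want:
                    raise GenerationError(
                        f"{leaf.path}: flank column {c} absent from layout")
                continue
            over[c] = "P" if c in want else _NONFLANK_DEFAULT[c]
    # extra cysteines
    for c in a.get("xcys", ()):
        if c not in cols:
            raise GenerationError(f"{leaf.path}: extra-Cys column {c} "
                                  "absent from layout")
        over[c] = "C"
    # site residues
    for c, v in a.get("pos", {}).items():
        if v == "-":
            if c in cols:
                raise GenerationError(
                    f"{leaf.path}: pos({c})=del but column occupied")
            continue
        if c not in cols:
            raise GenerationError(f"{leaf.path}: pos({c})={v} but column "
                                  "absent from layout")
        over[c] = _first(v)
    # terminal flags: the terminal residues are always pinned so a free
    # draw can never flip the amidation/pyroglutamate candidate calls
    last_col = lay.cols[-1]
    first_col = lay.cols[0]
    if a.get("cterm_gly") is not None:
        over.setdefault(last_col, "G" if a["cterm_gly"] else "N")
    if a.get("nterm_gln") is not None and first_col not in over:
        if a["nterm_gln"]:
            over[first_col] = "Q"
        elif leaf.family == "Colubrid":
            over[first_col] = "P" if a.get("procsite") not in (None, "none") \
                else "T"
    # dimer-model interfaces referenced by the predicate
    from .features import DIMER_MODELS
    for model in a.get("dimer", {}):
        for c, res in DIMER_MODELS[model].items():
            if c in cols:
                over.setdefault(c, res)
    # motif content
    if leaf.family == "Colubrid":
        want = set(a.get("motif+", ()))
        if "CGGHL" in want:              # class 11b: CYTLY replaced
            for c, r in zip((30, 31, 32, 33, 34), "CGGHL"):
                over[c] = r
            for c in (40, 41, 42, 43):   # and no WAVK-like segment either
                over.setdefault(c, "S")
        wavk = next((m for m in want if m.endswith("VK")), None)
        if wavk:
            start = 41 if leaf.layout_lengths()["loop2len"] == 16 else 40
            for c, r in zip(range(start, start + 4), wavk):
                over[c] = r
    if leaf.family == "NonConventional" and "RGD" in a.get("motif+", ()):
        for c, r in zip((35, 36, 37), "RGD"):
            over[c] = r
    return over


def _template_sequence(leaf: LeafSpec, rng: random.Random) -> str:
    lay = leaf.layout
    fam = SCAFFOLD[leaf.family]
    over = constrained_overrides(leaf)
    out = []
    for col in lay.cols:
        if col in over:
            out.append(over[col])
        elif col in CYS_ANCHOR_COLS:
            out.append("C")
        elif col in fam:
            out.append(fam[col])
        elif col < 1:
            out.append(NEUTRAL_ALPHABET[rng.randrange(len(NEUTRAL_ALPHABET))])
        else:
            out.append(FREE_ALPHABET[rng.randrange(len(FREE_ALPHABET))])
    seq = "".join(out)
    want = leaf.atoms["ncys"]
    if seq.count("C") != want:
        raise GenerationError(
            f"{leaf.path}: template has {seq.count('C')} Cys, ncys clause "
            f"requires {want}")
    return seq


def _propeptide(leaf: LeafSpec, rng: random.Random) -> str:
    spec = leaf.precursor
    if not spec:
        return ""
    motif = spec.get("motif", "")
    if spec["kind"] == "XaaGln":
        fill = spec["prop"]
    elif spec["kind"] == "pentabasic":
        motif = "RRKKK"
        fill = spec["prop"] - 5
    elif spec["kind"] == "tetrabasic":
        motif = "RRKK"
        fill = spec["prop"] - 4
    else:
        fill = spec["prop"] - len(motif)
    filler = "".join(NEUTRAL_ALPHABET[rng.randrange(len(NEUTRAL_ALPHABET))]
                     for _ in range(fill))
    return filler + motif


def generate_leaf(leaf: str | LeafSpec, seed: int, n: int = 1
                  ) -> list[ToxinRecord]:
    """Generate ``n`` fixtures for one leaf; reproducible under ``seed``."""
    if isinstance(leaf, str):
        leaf = leaf_by_path(leaf)
    records = []
    for k in range(n):
        rng = random.Random((seed, leaf.path, k).__repr__())
        mature = _template_sequence(leaf, rng)
        meta = {"truth": leaf.path, "synthetic": "1"}
        if leaf.atoms.get("covalent"):
            meta["covalent_dimer"] = "1"
        if leaf.family == "Colubrid":
            seq = _propeptide(leaf, rng) + mature
            rec = ToxinRecord(
                id=f"syn|{leaf.path}|{seed}.{k}", residues=seq,
                description=f"synthetic fixture for {leaf.path}",
                form="precursor_signal_removed", metadata=meta)
        else:
            rec = ToxinRecord(
                id=f"syn|{leaf.path}|{seed}.{k}", residues=mature,
                description=f"synthetic fixture for {leaf.path}",
                form="mature", metadata=meta)
        records.append(rec)
    return records


def generate_cohort(registry=None, seed: int = 0
                    ) -> tuple[list[ToxinRecord], dict[str, str]]:
    """One fixture per registry leaf plus an id -> leaf-path truth map."""
    paths = [l.path for l in LEAVES]
    if registry is not None:
        paths = [l.path for l in registry.leaves]
    records, truth = [], {}
    for path in paths:
        rec = generate_leaf(path, seed, 1)[0]
        records.append(rec)
        truth[rec.id] = path
    return records, truth


def mutate(record: ToxinRecord, columns: dict[int, str] | None = None,
           positions: dict[int, str] | None = None, rate: float = 0.0,
           seed: int = 0) -> ToxinRecord:
    """Substitute residues of a fixture.

    ``columns`` addresses frame columns of the fixture's template layout
    (explicit edits — constrained positions allowed); ``positions``
    addresses 1-based positions in the record.  ``rate`` applies seeded
    substitutions to unconstrained positions only, so the leaf label is
    preserved by construction.  The edit list is recorded in metadata.
    """
    truth = record.metadata.get("truth")
    leaf = leaf_by_path(truth) if truth else None
    seq = list(record.residues)
    offset = len(record.residues) - len(leaf.layout) if leaf else 0
    edits = []

    def setpos(pos: int, res: str):
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} out of range")
        edits.append(f"{seq[pos - 1]}{pos}{res}")
        seq[pos - 1] = res

    for col, res in (columns or {}).items():
        if leaf is None:
            raise ValueError("column addressing requires a fixture with a "
                             "truth label")
        p = leaf.layout.pos_of(col)
        if p is None:
            raise ValueError(f"column {col} not occupied by {truth}")
        setpos(p + offset, res)
    for pos, res in (positions or {}).items():
        setpos(pos, res)
    if rate:
        rng = random.Random((seed, record.id, "mut").__repr__())
        fixed = set()
        if leaf is not None:
            over = constrained_overrides(leaf)
            fixed = {leaf.layout.pos_of(c) + offset for c in over
                     if leaf.layout.pos_of(c) is not None}
            fixed |= {leaf.layout.pos_of(c) + offset
                      for c in CYS_ANCHOR_COLS if leaf.layout.pos_of(c)}
            fixed |= set(range(1, offset + 1))   # propeptide untouched
        for pos in range(1, len(seq) + 1):
            if pos in fixed or seq[pos - 1] == "C":
                continue
            if rng.random() < rate:
                choices = FREE_ALPHABET.replace(seq[pos - 1], "")
                setpos(pos, choices[rng.randrange(len(choices))])
    meta = dict(record.metadata)
    if edits:
        meta["edits"] = ",".join(edits)
    return ToxinRecord(id=record.id + ("|mut" if edits else ""),
                       residues="".join(seq), description=record.description,
                       form=record.form, metadata=meta)
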