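"""The master homology frame and Cys-anchored alignment onto it.

``MasterFrame`` is rebuilt only from the shipped anchor alignment; user
sequences never mutate it.  ``align_to_frame`` is a global (Needleman–Wunsch
style) alignment of a mature sequence against per-class column profiles with
a large Cys–Cys bonus on the eight anchor columns, affine gap costs, and
cheaper gap opening inside loop regions.  Frame columns that a profile does
not occupy cost nothing to skip, and leading/trailing frame columns are free
(N-terminal extensions and tail truncations).

The reported homology number of a residue is simply its frame column;
output notation is ``n(m)`` with ``(m)`` omitted when the numbers agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio.Align import substitution_matrices

from .layouts import CYS_ANCHOR_COLS, MAX_COL, MIN_COL, region_of
from .records import ToxinRecord

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _B62.alphabet


def _score(a: str, b: str) -> float:
    """Query residue vs profile column.

    Lowercase profile residues mark variable (background) columns: any
    residue there scores a flat occupancy reward, so the alignment register
    is pinned by the consensus columns and the Cys anchors alone.
    """
    if b.islower():
        return 1.0
    if a not in _B62_ALPHA or b not in _B62_ALPHA:
        return 0.0
    return float(_B62[a, b])


_LOOP_REGIONS = {"loop1", "loop2", "loop3", "ctail", "nterm_ext"}


def load_config(path: str | Path | None = None) -> dict:
    """Alignment parameters; defaults are frozen in the shipped config file."""
    if path is None:
        text = resources.files("tfx").joinpath("data/config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


class FrameBuildError(ValueError):
    """The anchor alignment violates a frame invariant."""


@dataclass
class FrameColumn:
    index: int                       # homology number (<= 0 in the extension)
    kind: str                        # cys_anchor | ordinary
    consensus: dict[str, int] = field(default_factory=dict)


@dataclass
class MasterFrame:
    """Global homology coordinate system seeded from the anchor alignment."""

    columns: dict[int, FrameColumn]
    anchor_toxins: dict[str, str]            # name -> gapped sequence
    profiles: list[tuple[str, str, tuple]]   # (name, family, ((col, res), ...))
    config: dict

    cys_anchor_indices: tuple[int, ...] = CYS_ANCHOR_COLS

    def seed_mapping(self, name: str) -> dict[int, int]:
        """Original position -> column mapping of an anchor-file sequence."""
        gapped_seq = self.anchor_toxins[name]
        out, pos = {}, 0
        for i, ch in enumerate(gapped_seq):
            if ch != "-":
                pos += 1
                out[pos] = MIN_COL + i
        return out


def _parse_header(desc: str) -> dict[str, str]:
    out = {}
    for tok in desc.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def build_master_frame(anchor_path: str | Path | None = None,
                       config: dict | None = None) -> MasterFrame:
    """Build the frame from the shipped (or a user-supplied) anchor alignment."""
    from Bio import SeqIO

    if anchor_path is None:
        anchor_path = resources.files("tfx").joinpath("data/anchors.afa")
    config = config or load_config()

    columns = {i: FrameColumn(i, "cys_anchor" if i in CYS_ANCHOR_COLS
                              else "ordinary")
               for i in range(MIN_COL, MAX_COL + 1)}
    anchor_toxins: dict[str, str] = {}
    profiles = []
    width = MAX_COL - MIN_COL + 1
    if isinstance(anchor_path, (str, Path)):
        entries = list(SeqIO.parse(str(anchor_path), "fasta"))
    else:  # packaged resource
        with resources.as_file(anchor_path) as p:
            entries = list(SeqIO.parse(str(p), "fasta"))
    if not entries:
        raise FrameBuildError(f"{anchor_path}: empty anchor alignment")
    for sr in entries:
        meta = _parse_header(sr.description)
        seq = str(sr.seq)
        if len(seq) != width:
            raise FrameBuildError(
                f"anchor {sr.id}: width {len(seq)} != frame width {width}")
        for col in CYS_ANCHOR_COLS:
            if seq[col - MIN_COL].upper() != "C":
                raise FrameBuildError(
                    f"anchor {sr.id}: no Cys in anchor column {col}")
        anchor_toxins[sr.id] = seq.upper()
        for i, ch in enumerate(seq.upper()):
            if ch != "-":
                col = columns[MIN_COL + i]
                col.consensus[ch] = col.consensus.get(ch, 0) + 1
        if meta.get("kind") == "exemplar":
            prof = tuple((MIN_COL + i, ch) for i, ch in enumerate(seq)
                         if ch != "-")
            profiles.append((sr.id, meta.get("family", "?"), prof))
    if not profiles:
        raise FrameBuildError("anchor alignment contains no exemplar profiles")
    return MasterFrame(columns, anchor_toxins, profiles, config)


@dataclass
class AlignedToxin:
    """A toxin mapped onto the master frame."""

    record: ToxinRecord
    col_of: dict[int, int]           # original position -> frame column
    res_at: dict[int, str]           # frame column -> residue
    score: float
    family: str
    profile: str
    flags: set[str] = field(default_factory=set)

    @property
    def anchors_matched(self) -> int:
        return sum(1 for c in CYS_ANCHOR_COLS if self.res_at.get(c) == "C")

    @property
    def unmatched_anchors(self) -> tuple[int, ...]:
        return tuple(c for c in CYS_ANCHOR_COLS if self.res_at.get(c) != "C")

    def homology_label(self, pos: int) -> str:
        """The dual-number notation n(m), with (m) omitted when m == n."""
        col = self.col_of.get(pos)
        if col is None or col == pos:
            return str(pos)
        return f"{pos}({col})"


@dataclass
class LoopPartition:
    """Original-position intervals of the three loops, half-open [start, stop)."""

    nterm: tuple[int, int] | None
    loop1: tuple[int, int] | None
    loop2: tuple[int, int] | None
    loop3: tuple[int, int] | None
    ctail: tuple[int, int] | None

    def length(self, name: str) -> int | None:
        iv = getattr(self, name)
        return None if iv is None else iv[1] - iv[0]


def _gap_open(cfg: dict, col: int) -> float:
    return cfg["gap_open_loop"] if region_of(col) in _LOOP_REGIONS \
        else cfg["gap_open_core"]


def _straight_scores(query: str, prof: tuple, cfg: dict):
    """Best contiguous (indel-free) placements of query along the profile."""
    n, m = len(query), len(prof)
    bonus = cfg["anchor_bonus"]
    best = None
    for off in range(0, m - n + 1):
        s = 0.0
        for i, q in enumerate(query):
            col, res = prof[off + i]
            s += _score(q, res)
            if col in CYS_ANCHOR_COLS and q == "C":
                s += bonus
        if best is None or s > best[0]:
            best = (s, off)
    return best  # may be None when n > m


def _dp_align(query: str, prof: tuple, cfg: dict):
    """Affine-gap global alignment of query against one column profile.

    Leading/trailing profile columns are free; interior profile-column gaps
    and query insertions are affine.  Ties prefer match, then column
    deletion, then insertion (leftmost-gap placement).
    """
    n, m = len(query), len(prof)
    NEG = float("-inf")
    bonus = cfg["anchor_bonus"]
    go_ins, ge_ins = cfg["gap_open_core"], cfg["gap_extend"]
    ge = cfg["gap_extend"]
    opens = [_gap_open(cfg, col) for col, _ in prof]

    # matrices indexed [i][j]: i query residues, j profile columns consumed
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in query (skip column)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # insertion (extra residue)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = 0.0                              # free leading columns
    for i in range(1, n + 1):
        Y[i][0] = (go_ins if i == 1 else 0) + ge_ins * i

    for i in range(1, n + 1):
        q = query[i - 1]
        for j in range(1, m + 1):
            col, res = prof[j - 1]
            sub = _score(q, res)
            if col in CYS_ANCHOR_COLS and q == "C":
                sub += bonus
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + sub if diag > NEG else NEG
            xo = max(M[i][j - 1] + opens[j - 1] + ge, X[i][j - 1] + ge,
                     Y[i][j - 1] + opens[j - 1] + ge)
            X[i][j] = xo
            yo = max(M[i - 1][j] + go_ins + ge_ins, Y[i - 1][j] + ge_ins,
                     X[i - 1][j] + go_ins + ge_ins)
            Y[i][j] = yo

    # free trailing columns: end in any (n, j) state
    best_j, best_s, best_mat = None, NEG, "M"
    for j in range(m + 1):
        for mat, val in (("M", M[n][j]), ("Y", Y[n][j])):
            v = val
            if v > best_s:
                best_s, best_j, best_mat = v, j, mat
    # traceback
    mapping: dict[int, int] = {}
    i, j, mat = n, best_j, best_mat
    while i > 0:
        if mat == "M":
            col, res = prof[j - 1]
            q = query[i - 1]
            sub = _score(q, res) + (cfg["anchor_bonus"]
                                    if col in CYS_ANCHOR_COLS and q == "C" else 0)
            mapping[i] = col
            prev = M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            tgt = M[i][j] - sub
            mat = ("M", "X", "Y")[max(range(3),
                                      key=lambda k: (abs(prev[k] - tgt) < 1e-9, -k))]
            i, j = i - 1, j - 1
        elif mat == "X":
            # column skipped
            tgt = X[i][j]
            cand = (M[i][j - 1] + opens[j - 1] + ge, X[i][j - 1] + ge,
                    Y[i][j - 1] + opens[j - 1] + ge)
            mat = ("M", "X", "Y")[max(range(3),
                                      key=lambda k: (abs(cand[k] - tgt) < 1e-9, -k))]
            j -= 1
        else:  # Y: query insertion, no column
            tgt = Y[i][j]
            cand = (M[i - 1][j] + go_ins + ge_ins, Y[i - 1][j] + ge_ins,
                    X[i - 1][j] + go_ins + ge_ins)
            mat = ("M", "Y", "X")[max(range(3),
                                      key=lambda k: (abs(cand[k] - tgt) < 1e-9, -k))]
            i -= 1
    return best_s, mapping


def align_to_frame(record: ToxinRecord, frame: MasterFrame) -> AlignedToxin:
    """Globally align a mature sequence onto the frame.

    Every per-class profile is screened with an indel-free scan; the best
    candidates are then refined by full dynamic programming.  Deterministic
    for fixed parameters.  Sequences that cannot place a Cys in every anchor
    column come back flagged ``anchor_incomplete`` rather than failing.
    """
    if record.form != "mature":
        raise ValueError("align_to_frame expects a mature sequence; "
                         "process precursors first")
    cfg = frame.config
    query = record.residues

    screened = []
    for name, family, prof in frame.profiles:
        hit = _straight_scores(query, prof, cfg)
        if hit is not None:
            screened.append((hit[0], name, family, prof, hit[1]))
    # ties (profiles sharing a body) go to the closest-length profile
    screened.sort(key=lambda t: (-t[0], abs(len(t[3]) - len(query)), t[1]))

    k = cfg.get("dp_candidates", 6)
    candidates = screened[:k] if screened else [
        (float("-inf"), name, family, prof, None)
        for name, family, prof in frame.profiles]

    best = None
    for s0, name, family, prof, off in candidates:
        score, mapping = _dp_align(query, prof, cfg)
        if best is None or score > best[0]:
            best = (score, name, family, mapping)
    score, prof_name, family, mapping = best

    res_at = {col: query[pos - 1] for pos, col in mapping.items()}
    aligned = AlignedToxin(record=record, col_of=mapping, res_at=res_at,
                           score=score, family=family, profile=prof_name)
    if aligned.anchors_matched < 8:
        aligned.flags.add("anchor_incomplete")
    if len(mapping) < len(query):
        aligned.flags.add("unaligned_insertions")
    return aligned


def partition_loops(aligned: AlignedToxin) -> LoopPartition:
    """Loop intervals by Cys ordinals: loop I between Cys#1/#2, loop II
    between Cys#3/#4, loop III between Cys#5/#6; tail after Cys#8.

    Anchor-incomplete alignments yield a partial partition with the affected
    intervals set to None.
    """
    n = len(aligned.record.residues)

    def pos_at(col):
        for p, c in aligned.col_of.items():
            if c == col:
                return p
        return None

    anchors = {c: pos_at(c) for c in CYS_ANCHOR_COLS}

    def iv(a_col, b_col):
        pa, pb = anchors[a_col], anchors[b_col]
        if pa is None or pb is None or aligned.res_at.get(a_col) != "C" \
                or aligned.res_at.get(b_col) != "C":
            return None
        return (pa + 1, pb)

    p1 = anchors[3]
    nterm = (1, p1) if p1 is not None and aligned.res_at.get(3) == "C" else None
    p8 = anchors[66]
    ctail = (p8 + 1, n + 1) if p8 is not None \
        and aligned.res_at.get(66) == "C" else None
    return LoopPartition(nterm=nterm, loop1=iv(3, 17), loop2=iv(24, 45),
                         loop3=iv(47, 60), ctail=ctail)
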