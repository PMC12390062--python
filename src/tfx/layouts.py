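"""Global homology-frame geometry for three-finger toxins (3FTxs).

The frame is a single cross-family coordinate system.  Canonical columns are
1..92 and match the bracketed homology numbers the field uses for short- and
long-chain alpha-neurotoxin positions (e.g. the loop II arginine of
erabutoxin a, original residue 33, sits in column 37).  Colubrid toxins carry
an N-terminal extension ahead of the canonical start; extension columns are
numbered <= 0, with 0 the residue immediately preceding canonical column 1.

Eight cysteine columns are anchors common to all families:

    C1=3  C2=17  C3=24  C4=45  C5=47  C6=60  C7=61  C8=66

Family-specific extra cysteines (the long-chain loop II pair, the
non-conventional loop I pair, free thiols, interchain cysteines) occupy
ordinary columns.  A ``Layout`` fixes, for one structural class, which column
every residue of a mature sequence occupies.  Distinct families place
residues on their own columns; homologous residues of two families need not
share a column, exactly as the per-family bracketed numbering does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# anchor columns of the eight conserved cysteines
CYS_ANCHOR_COLS: tuple[int, ...] = (3, 17, 24, 45, 47, 60, 61, 66)

MIN_COL = -16          # deepest N-terminal extension column (17 residues)
MAX_COL = 92

# region boundaries in frame columns (half-open on neither side; inclusive)
REGIONS = {
    "nterm_ext": (MIN_COL, 0),
    "pre_loop1": (1, 2),
    "loop1": (4, 16),
    "inter12": (18, 23),
    "loop2": (25, 44),
    "inter23": (46, 46),
    "loop3": (48, 59),
    "inter34": (62, 65),
    "ctail": (67, MAX_COL),
}

# loop II tip pair of long-chain (Type II) toxins — the "fifth disulfide"
LOOP2_EXTRA_CYS = (30, 34)
# loop I pair of non-conventional/colubrid toxins
LOOP1_EXTRA_CYS = (6, 13)

# proline flank columns referenced by the classification criteria
FLANK_COLS = (7, 11, 12, 50, 54)


def region_of(col: int) -> str:
    """Name of the frame region containing ``col`` ('anchor' for Cys columns)."""
    if col in CYS_ANCHOR_COLS:
        return "anchor"
    for name, (lo, hi) in REGIONS.items():
        if lo <= col <= hi:
            return name
    raise ValueError(f"column {col} outside frame")


@dataclass(frozen=True)
class Layout:
    """Column occupancy of one structural class.

    ``cols[i]`` is the frame column of mature residue ``i + 1`` (1-based
    original numbering, N-terminal extension included for colubrids).
    """

    name: str
    family: str
    cols: tuple[int, ...]
    _col_to_pos: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if list(self.cols) != sorted(set(self.cols)):
            raise ValueError(f"layout {self.name}: columns not strictly increasing")
        object.__setattr__(self, "_col_to_pos",
                           {c: i + 1 for i, c in enumerate(self.cols)})

    def __len__(self) -> int:
        return len(self.cols)

    def pos_of(self, col: int) -> int | None:
        """Original position at ``col``, or None if the column is a gap."""
        return self._col_to_pos.get(col)

    @property
    def anchor_positions(self) -> tuple[int | None, ...]:
        return tuple(self.pos_of(c) for c in CYS_ANCHOR_COLS)


def _cols(*parts) -> tuple[int, ...]:
    out: list[int] = []
    for p in parts:
        if isinstance(p, int):
            out.append(p)
        elif (isinstance(p, tuple) and len(p) == 2
              and all(isinstance(x, int) for x in p)):
            out.extend(range(p[0], p[1] + 1))
        else:
            out.extend(_cols(*p))
    return tuple(out)


def _tail(n: int, *, skip69: bool = False) -> tuple[int, ...]:
    """C-terminal tail columns after the last anchor (column 66)."""
    if n == 0:
        return ()
    if skip69 and n > 2:
        # long-chain convention: the aromatic His/Phe of the tail sits in
        # column 70 as its third tail residue, so column 69 stays open
        return _cols((67, 68), (70, 67 + n))
    return tuple(range(67, 67 + n))


_CORE = ((1, 2), 3)                     # two N-terminal residues + C1
_INTER12_FULL = ((18, 23),)             # six residues between C2 and C3
_C45 = (45, 46, 47)                     # C4 - x - C5
_POST = (60, 61, (62, 65), 66)          # C6 C7 - four residues - C8

_L1_FULL = ((4, 16),)                   # 13-residue loop I (short-chain)
_L1_9 = ((4, 7), (12, 16))              # 9 residues
_L1_8 = ((4, 7), (13, 16))              # 8 residues (omega)
_L1_10 = ((4, 7), (11, 16))             # 10 residues (long-chain)
_L1_11 = ((4, 8), (11, 16))             # 11 residues (non-conventional)

_L2_TI = ((25, 31), (36, 44))           # 16 residues, short-chain
_L3_TI = ((50, 59),)                    # 10 residues, short-chain


def _layout(name, family, *parts) -> Layout:
    return Layout(name, family, _cols(*parts))


def _colubrid(name: str, ext: int, tail: int, *, short_loop2: bool = False) -> Layout:
    loop2 = ((25, 36), (41, 44)) if short_loop2 else ((25, 44),)
    return _layout(
        name, "Colubrid",
        (1 - ext, 0) if ext else (),
        _CORE, *_L1_11, 17, *_INTER12_FULL, 24, *loop2, _C45, *_L3_TI,
        *_POST, _tail(tail),
    )


LAYOUTS: dict[str, Layout] = {lay.name: lay for lay in [
    # ---- Type I (short-chain) ----
    _layout("TI_STD", "TypeI",
            _CORE, *_L1_FULL, 17, *_INTER12_FULL, 24, *_L2_TI, _C45,
            *_L3_TI, *_POST, _tail(2)),
    _layout("TI_C4", "TypeI",                      # loop II tip deletions
            _CORE, *_L1_FULL, 17, *_INTER12_FULL, 24, (25, 30), (38, 44),
            _C45, *_L3_TI, *_POST, _tail(2)),
    _layout("TI_C5", "TypeI",                      # short loop I, long tail
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 31), (37, 44),
            _C45, *_L3_TI, *_POST, _tail(9)),
    _layout("TI_C6", "TypeI",                      # short loop I, long loop II
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 44),
            _C45, *_L3_TI, *_POST, _tail(24)),
    _layout("TI_C8", "TypeI",                      # hybrid: full loop I + tail
            _CORE, *_L1_FULL, 17, *_INTER12_FULL, 24, *_L2_TI,
            _C45, *_L3_TI, *_POST, _tail(9)),
    # ---- Type II (long-chain); tails truncate from the right ----
    _layout("TII_STD", "TypeII",
            _CORE, *_L1_10, 17, (18, 22), 24, (25, 44),
            _C45, (48, 59), *_POST, _tail(24, skip69=True)),
    # ---- Type III ----
    _layout("TIII_1A", "TypeIII",
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 31), (35, 42),
            _C45, (50, 56), *_POST, _tail(6)),
    _layout("TIII_1B", "TypeIII",                  # lacks the column-37 Gly
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 31), 35, 36, (38, 42),
            _C45, (50, 56), *_POST, _tail(6)),
    _layout("TIII_2", "TypeIII",                   # extended C-terminal tail
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 31), (35, 42),
            _C45, (50, 56), *_POST, _tail(11)),
    # ---- Non-conventional (fifth disulfide in loop I) ----
    _layout("NC1", "NonConventional",              # candoxin-like
            _CORE, *_L1_11, 17, *_INTER12_FULL, 24, (25, 34), (39, 44),
            _C45, (50, 59), *_POST, _tail(6)),
    _layout("NC2", "NonConventional",              # gamma-bungarotoxin-like
            _CORE, *_L1_11, 17, *_INTER12_FULL, 24, (25, 44),
            _C45, (54, 59), *_POST, _tail(6)),
    _layout("NC3", "NonConventional",              # WTX-like
            _CORE, *_L1_11, 17, *_INTER12_FULL, 24, (25, 33), (37, 44),
            _C45, (51, 59), *_POST, _tail(7)),
    _layout("NC4", "NonConventional",              # long-loop class
            _CORE, *_L1_FULL, 17, *_INTER12_FULL, 24, (25, 42),
            _C45, (50, 59), *_POST, _tail(6)),
    # ---- Omega ----
    _layout("OM", "Omega",
            _CORE, *_L1_8, 17, *_INTER12_FULL, 24, (25, 34), (38, 44),
            _C45, (48, 54), *_POST, _tail(4)),
    # ---- Sigma ----
    _layout("SG", "Sigma",
            _CORE, *_L1_9, 17, *_INTER12_FULL, 24, (25, 35), (39, 44),
            _C45, (53, 59), *_POST, _tail(5)),
    # ---- Colubrid ----
    _colubrid("CO_STD", 17, 9),
    _colubrid("CO_1B", 7, 2, short_loop2=True),    # four-residue-shorter loop II
    # ---- rarer class geometries ----
    # Type I class 2e: full loop I plus a Gly/Ser-rich 19-residue loop II
    _layout("TI_2E", "TypeI",
            _CORE, *_L1_FULL, 17, *_INTER12_FULL, 24, (25, 31), (33, 44),
            _C45, (50, 59), *_POST, _tail(2)),
    # Type II class 2c(xiii): loop II deletions around the tip
    _layout("TII_X13", "TypeII",
            _CORE, *_L1_10, 17, (18, 22), 24, (25, 37), (40, 44),
            _C45, (48, 59), *_POST, _tail(9, skip69=True)),
    # non-conventional class 1c: the loop II His sits one column later
    _layout("NC1C", "NonConventional",
            _CORE, *_L1_11, 17, *_INTER12_FULL, 24, (25, 33), (38, 44),
            _C45, (50, 59), *_POST, _tail(6)),
    # non-conventional class 3c(v): two loop II deletions
    _layout("NC3V", "NonConventional",
            _CORE, *_L1_11, 17, *_INTER12_FULL, 24, (25, 30), (32, 33),
            (38, 44), _C45, (51, 59), *_POST, _tail(7)),
]}


def colubrid_layout(ext: int, tail: int, *, short_loop2: bool = False) -> Layout:
    """Colubrid layout with a given N-terminal extension and tail length."""
    return _colubrid(f"CO_e{ext}t{tail}{'s' if short_loop2 else ''}",
                     ext, tail, short_loop2=short_loop2)


def truncated(base: Layout, tail: int) -> Layout:
    """Layout equal to ``base`` with its tail cut to ``tail`` residues."""
    body = tuple(c for c in base.cols if c < 67)
    full_tail = tuple(c for c in base.cols if c >= 67)
    if tail > len(full_tail):
        raise ValueError(f"{base.name}: tail {tail} exceeds layout tail")
    return Layout(f"{base.name}_t{tail}", base.family, body + full_tail[:tail])
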