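"""Family scaffolds: residue content on top of the column layouts.

A scaffold maps frame columns to default residues for one family — the
conserved cysteines, the family's typical functional-site residues, and a
neutral deterministic background elsewhere.  Scaffolds are the source of the
shipped anchor alignment, of the per-class alignment profiles, and of the
synthetic fixture generator.  All sequences built here are synthetic
stand-ins constructed to satisfy the published residue/homology-number
constraints; they are not real venom sequences.
"""

from __future__ import annotations

from .layouts import (CYS_ANCHOR_COLS, LAYOUTS, LOOP1_EXTRA_CYS,
                      LOOP2_EXTRA_CYS, Layout, colubrid_layout, truncated)

# background alphabet for unconstrained positions; C (cysteine topology),
# W (motif content) and P (flanking-proline calls) are placed only explicitly
BACKGROUND = "ASTGNDEKQLIVRHFYM"

# deterministic neutral residue per column (sequence-like, non-C/W/P)
_BG_CYCLE = "TNSGKEALIQDVSTGNKEAHLSIVTDGKNSELAQTIGSKDNALEVTSGIKQ"


def background_residue(col: int) -> str:
    return _BG_CYCLE[(col + 40) % len(_BG_CYCLE)]


# family-typical residues at criteria columns (defaults; leaves override)
SCAFFOLD: dict[str, dict[int, str]] = {
    "TypeI": {1: "R", 2: "I", 7: "Q", 8: "S", 9: "S", 10: "Q", 11: "P",
              12: "T", 23: "I", 27: "K", 29: "W", 31: "D", 36: "F", 37: "R",
              38: "G", 40: "I", 42: "E", 50: "P", 53: "K", 54: "P", 70: "H"},
    "TypeII": {1: "I", 2: "R", 27: "K", 29: "W", 30: "C", 31: "D", 32: "A",
               33: "F", 34: "C", 37: "R", 39: "K", 40: "V", 50: "P",
               53: "K", 54: "P", 58: "S", 59: "N", 70: "H"},
    "TypeIII": {1: "R", 2: "T", 37: "G", 71: "L"},
    "NonConventional": {1: "L", 2: "T", 6: "C", 13: "C", 29: "E", 31: "W",
                        33: "E", 34: "A", 35: "A", 37: "A", 38: "A",
                        39: "R", 41: "A", 42: "R", 44: "E", 55: "S"},
    "Omega": {1: "T", 2: "K", 7: "H", 27: "K", 28: "T", 29: "T", 30: "M",
              31: "F", 32: "F", 33: "P", 38: "H", 39: "P", 53: "K", 54: "Y"},
    "Sigma": {1: "R", 2: "T", 21: "E", 26: "I", 29: "L", 30: "G", 31: "F",
              33: "H", 34: "I", 42: "I", 44: "T", 71: "G"},
    "Colubrid": {1: "T", 2: "E", 6: "C", 13: "C", 30: "C", 31: "Y", 32: "T",
                 33: "L", 34: "Y", 40: "W", 41: "A", 42: "V", 43: "K",
                 50: "P", 53: "K", 54: "P"},
}


def build_sequence(layout: Layout, family: str,
                   overrides: dict[int, str] | None = None) -> str:
    """Residue string for ``layout`` from scaffold + overrides."""
    overrides = overrides or {}
    fam = SCAFFOLD[family]
    out = []
    for col in layout.cols:
        if col in overrides:
            out.append(overrides[col])
        elif col in CYS_ANCHOR_COLS:
            out.append("C")
        elif col in fam:
            out.append(fam[col])
        else:
            out.append(background_residue(col))
    return "".join(out)


def gapped(layout: Layout, seq: str) -> str:
    """A2M-style gapped string of ``seq`` over the full frame column range."""
    from .layouts import MAX_COL, MIN_COL
    chars = {c: seq[i] for i, c in enumerate(layout.cols)}
    return "".join(chars.get(c, "-") for c in range(MIN_COL, MAX_COL + 1))


#: class-typical residues that distinguish sibling geometries sharing
#: identical segment lengths (the loop II His register of class 1c)
EXEMPLAR_OVERRIDES: dict[str, dict[int, str]] = {
    "NC1C": {38: "H"},
}


def exemplar_gapped(name: str, layout: Layout, family: str) -> str:
    """Gapped exemplar with consensus columns uppercase and variable
    (background) columns lowercase; lowercase columns score occupancy only
    during alignment."""
    from .layouts import MAX_COL, MIN_COL
    fam = SCAFFOLD[family]
    over = EXEMPLAR_OVERRIDES.get(name, {})
    chars = {}
    for col in layout.cols:
        if col in over:
            chars[col] = over[col]
        elif col in CYS_ANCHOR_COLS:
            chars[col] = "C"
        elif col in fam and col < 67:
            # the tail has no downstream anchor to pin its register, so all
            # tail columns stay neutral; consensus residues there would let
            # a chance match pay for a register shift
            chars[col] = fam[col]
        else:
            chars[col] = background_residue(col).lower()
    return "".join(chars.get(c, "-") for c in range(MIN_COL, MAX_COL + 1))


# ---------------------------------------------------------------------------
# exemplar geometries used as alignment profiles (one per structural class)
# ---------------------------------------------------------------------------

def _exemplar_layouts() -> dict[str, Layout]:
    ex = dict(LAYOUTS)
    ex["CO_STD"] = LAYOUTS["CO_STD"]
    return ex


EXEMPLAR_LAYOUTS: dict[str, Layout] = _exemplar_layouts()


def exemplar_sequences() -> dict[str, tuple[str, str]]:
    """name -> (family, sequence) for every exemplar geometry."""
    out = {}
    for name, lay in EXEMPLAR_LAYOUTS.items():
        out[name] = (lay.family, build_sequence(lay, lay.family))
    return out


# ---------------------------------------------------------------------------
# named anchor toxins (synthetic calibrated stand-ins)
# ---------------------------------------------------------------------------

def _anchor_defs() -> dict[str, tuple[Layout, str, dict[int, str]]]:
    TII = LAYOUTS["TII_STD"]
    return {
        # short-chain reference; the classical loop I/II/III site residues
        "erabutoxin_a": (LAYOUTS["TI_STD"], "TypeI", {}),
        # long-chain reference, alpha-7/muscle dual binder
        "alpha-cobratoxin": (truncated(TII, 9), "TypeII",
                             {40: "R", 70: "F"}),
        # krait long-chain toxin with the His/Val loop II signature
        "alpha-bungarotoxin": (truncated(TII, 9), "TypeII",
                               {33: "H", 32: "S", 76: "G"}),
        # non-covalent dimer, short tail, Arg in loop III
        "kappa-bungarotoxin": (truncated(TII, 2), "TypeII",
                               {29: "Q", 52: "F", 53: "R", 58: "L"}),
        # weak toxin, fifth disulfide in loop I, basic loop II pair
        "WTX": (LAYOUTS["NC3"], "NonConventional",
                {29: "K", 31: "H", 33: "R", 37: "R", 41: "W", 55: "K"}),
        # reversible muscle/alpha-7 blocker with loop I fifth disulfide
        "candoxin": (LAYOUTS["NC1"], "NonConventional", {}),
        # omega family reference (muscle and alpha3beta2 blocker)
        "Oh9-1": (LAYOUTS["OM"], "Omega", {}),
        # sigma family reference, Zn-binding dimer, terminal Gly
        "fulditoxin": (LAYOUTS["SG"], "Sigma", {}),
        # colubrid monomeric class reference, pyroGlu start, 7-residue ext
        "denmotoxin": (colubrid_layout(7, 2), "Colubrid", {-6: "Q"}),
    }


def anchor_sequences() -> dict[str, tuple[str, str, Layout]]:
    """name -> (family, sequence, layout) for the nine named anchors."""
    out = {}
    for name, (lay, family, over) in _anchor_defs().items():
        out[name] = (family, build_sequence(lay, family, over), lay)
    return out
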