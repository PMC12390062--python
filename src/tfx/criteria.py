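"""The 158-leaf taxonomy: family / class / group / subgroup criteria.

Per-family subgroup totals follow the running-text enumeration:

    Type I 36, Type II 56, Type III 3, non-conventional 20,
    omega 5, sigma 7, colubrid 31  (total 158)

Every leaf carries a full fingerprint: all of its family's decision atoms
are pinned, so sibling leaves always differ in at least one atom value and
a generated fixture satisfies exactly one leaf.  Loop lengths and tail
lengths are derived from the leaf's column layout, which keeps predicates
and the fixture generator consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dsl import Clause, Predicate
from .layouts import LAYOUTS, Layout, colubrid_layout, truncated

ALL_LAYOUTS = LAYOUTS


@dataclass
class LeafSpec:
    family: str
    cls: str
    group: str
    subgroup: str
    layout: Layout
    atoms: dict
    note: str
    exemplar: str | None = None
    precursor: dict | None = None      # colubrid propeptide construction

    @property
    def path(self) -> str:
        parts = [self.family, self.cls]
        if self.group:
            parts.append(self.group)
        if self.subgroup:
            parts.append(self.subgroup)
        return "/".join(parts)

    def layout_lengths(self) -> dict[str, int]:
        cols = self.layout.cols
        return {
            "loop1len": sum(1 for c in cols if 4 <= c <= 16),
            "loop2len": sum(1 for c in cols if 25 <= c <= 44),
            "loop3len": sum(1 for c in cols if 48 <= c <= 59),
            "ctail": sum(1 for c in cols if c >= 67),
        }

    def clauses(self) -> Predicate:
        a = self.atoms
        cl: list[Clause] = []
        cl.append(Clause("ncys", None, a["ncys"]))
        cl.append(Clause("anchors", None, a.get("anchors", 8)))
        cl.append(Clause("fifth", None, a["fifth"]))
        for c in a.get("xcys", ()):
            cl.append(Clause("xcys", c, True))
        lens = self.layout_lengths()
        for key in ("loop1len", "loop2len", "loop3len"):
            if not a.get("skip_" + key):
                cl.append(Clause(key, None, lens[key]))
        if not a.get("skip_ctail"):
            cl.append(Clause("ctail", None, lens["ctail"]))
        if a.get("next") is not None:
            cl.append(Clause("nterm_ext", None, a["next"]))
        if a.get("procsite") is not None:
            cl.append(Clause("procsite", None, a["procsite"]))
        if a.get("procmotif") is not None:
            v = a["procmotif"]
            cl.append(Clause("procmotif", None,
                             frozenset(v) if isinstance(v, tuple) else v))
        for col in sorted(a.get("pos", {})):
            v = a["pos"][col]
            cl.append(Clause("pos", col,
                             frozenset(v) if isinstance(v, tuple) else v))
        if a.get("proflanks") is not None:
            cl.append(Clause("proflanks", None, frozenset(a["proflanks"])))
        for m in a.get("motif+", ()):
            cl.append(Clause("motif", m, True))
        for m in a.get("motif-", ()):
            cl.append(Clause("motif", m, False))
        if a.get("cterm_gly") is not None:
            cl.append(Clause("cterm_gly", None, a["cterm_gly"]))
        if a.get("nterm_gln") is not None:
            cl.append(Clause("nterm_gln", None, a["nterm_gln"]))
        for model in sorted(a.get("dimer", {})):
            cl.append(Clause("dimer", model, a["dimer"][model]))
        if a.get("covalent") is not None:
            cl.append(Clause("covalent", None, a["covalent"]))
        return Predicate(tuple(cl))


def _merge(base: dict, **over) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in over.items():
        if k == "pos":
            out.setdefault("pos", {}).update(v)
        else:
            out[k] = v
    return out


LEAVES: list[LeafSpec] = []


def _leaf(family, cls, group, subgroup, layout, atoms, note,
          exemplar=None, precursor=None):
    LEAVES.append(LeafSpec(family, cls, group, subgroup, layout, atoms,
                           note, exemplar, precursor))


# ===========================================================================
# Type I (short-chain): 36 subgroups
# ===========================================================================

_TI = {
    "ncys": 8, "fifth": "none", "cterm_gly": False,
    "pos": {7: "Q", 8: "S", 10: "Q", 27: "K", 29: "W", 31: "D", 36: "F",
            37: "R", 40: "I", 42: "E", 53: "K", 70: "-"},
    "proflanks": (11, 50, 54),
}

TI_STD = LAYOUTS["TI_STD"]


def _ti(cls, group, subgroup, note, layout=TI_STD, exemplar=None, **over):
    _leaf("TypeI", cls, group, subgroup, layout, _merge(_TI, **over), note,
          exemplar)


_ti("1", "1a", "", "erabutoxin-like: all ten functional residues, "
    "Pro11/Pro50/Pro54 flanks", exemplar="erabutoxin a")
_ti("1", "1b", "i", "Phe36 replaced by His36", pos={36: "H"})
_ti("1", "1b", "ii", "Gln10 replaced by Glu10", pos={10: "E"})
_ti("1", "1b", "iii", "loop I flanking Pro11 missing", proflanks=(50, 54))
_ti("1", "1b", "iv", "loop III flanking Pro54 missing", proflanks=(11, 50))
_ti("1", "1c", "i", "Pro12 instead of Pro11, all three flanks",
    proflanks=(12, 50, 54))
_ti("1", "1c", "ii", "Pro12/Pro50 only, Ile40 to Arg40",
    proflanks=(12, 50), pos={40: "R"})
_ti("1", "1c", "iii", "Pro12/Pro50, Arg40 and acidic Glu10",
    proflanks=(12, 50), pos={40: "R", 10: "E"})
_ti("1", "1d", "i", "both Pro11 and Pro12 in loop I",
    proflanks=(11, 12, 50, 54))
_ti("1", "1d", "ii", "Pro11+Pro12 with Glu10",
    proflanks=(11, 12, 50, 54), pos={10: "E"})
_ti("1", "1d", "iii", "Pro11+Pro12, Ser8 to Thr8, Pro54 to Leu54",
    proflanks=(11, 12, 50), pos={8: "T", 54: "L"})
_ti("1", "1d", "iv", "C-terminal Gly (amidation candidate)",
    proflanks=(11, 12, 50, 54), cterm_gly=True)
_ti("1", "1d", "v", "C-terminal Gly with loop III Lys53 lost",
    proflanks=(11, 12, 50, 54), cterm_gly=True, pos={53: ("I", "N")})
_ti("1", "1e", "", "Pro7 and Pro11 bracketing the loop I site",
    proflanks=(7, 11, 50, 54), pos={7: "P"})
_ti("1", "1f", "", "only Pro50; Phe36 to Gly/Ile; Arg40",
    proflanks=(50,), pos={36: ("G", "I"), 40: "R"})
_ti("1", "1g", "", "Gln10 to Thr10", pos={10: "T"})
_ti("1", "1h", "", "four functional residues retained; Asn10, Lys40",
    pos={10: "N", 40: "K"})
_ti("1", "1i", "", "only a few functional residues conserved",
    proflanks=(), pos={7: "T", 10: "A", 27: "S", 36: "L", 53: "N"})

_ti("2", "2a", "", "free-thiol Cys4 with Phe36 and Arg40",
    ncys=9, xcys=(4,), pos={40: "R"})
_ti("2", "2b", "", "Cys4 with His36",
    ncys=9, xcys=(4,), pos={36: "H", 40: "R"})
_ti("2", "2c", "", "Cys4; Pro54 substituted (Ser/Thr/His/Arg)",
    ncys=9, xcys=(4,), proflanks=(11, 50), pos={54: ("S", "T", "H", "R")})
_ti("2", "2d", "", "Cys4; Met27, Gly31, Ile36, His37",
    ncys=9, xcys=(4,), pos={27: "M", 31: "G", 36: "I", 37: "H"})
_ti("2", "2e", "", "Cys4 with a long Gly/Ser-rich loop II",
    layout=ALL_LAYOUTS["TI_2E"], ncys=9, xcys=(4,),
    pos={27: "G", 31: "G", 36: "G", 37: "H", 40: "S", 42: "S"})

_ti("3", "3a", "", "ten Cys (Cys4+Cys16); all ten functional residues",
    ncys=10, xcys=(4, 16))
_ti("3", "3b", "", "ten Cys; only part of the site retained",
    ncys=10, xcys=(4, 16), pos={7: "L", 8: "G", 10: "A", 42: "Q"})

_ti("4", "", "", "loop II tip (Asp31/Phe36/Arg37) deleted; Pro-Pro "
    "around Lys53", layout=LAYOUTS["TI_C4"],
    pos={31: "-", 36: "-", 37: "-"}, proflanks=(50, 54))

for grp, r27 in (("5a", "K"), ("5b", "R"), ("5c", "E")):
    _ti("5", grp, "", f"short loop I, His70 tail; loop II site with "
        f"{r27}27", layout=LAYOUTS["TI_C5"],
        pos={7: "T", 8: "-", 10: "-", 27: r27, 36: "-", 70: "H"},
        proflanks=(50, 54))

for grp, t in (("6a", 7), ("6b", 10), ("6c", 13), ("6d", 24)):
    _ti("6", grp, "", f"short loop I, long Gly/Ser loop II, {t}-residue "
        "tail with Phe70", layout=truncated(LAYOUTS["TI_C6"], t),
        pos={7: "T", 8: "-", 10: "-", 36: "H", 70: "F"},
        proflanks=(50, 54))

_ti("7", "", "", "like class 6 but Thr/Ser at position 36 and His70",
    layout=truncated(LAYOUTS["TI_C6"], 7),
    pos={7: "T", 8: "-", 10: "-", 36: ("T", "S"), 70: "H"},
    proflanks=(50, 54))
_ti("8", "", "", "short-chain loops I/II with a long-chain His70 tail",
    layout=LAYOUTS["TI_C8"], pos={70: "H"})
_ti("9", "", "", "haditoxin-like non-covalent homodimer",
    pos={27: "T", 36: "A", 40: "R", 54: "L"}, proflanks=(11, 50),
    dimer={"haditoxin": 0.8}, exemplar="haditoxin")

# ===========================================================================
# Type II (long-chain): 56 subgroups
# ===========================================================================

_TII = {
    "ncys": 10, "fifth": "2", "cterm_gly": False, "covalent": False,
    "pos": {27: "K", 29: "W", 31: "D", 32: "A", 33: "F", 37: "R", 40: "V",
            53: "K", 70: "H"},
    "proflanks": (50, 54),
}

_TIIL = LAYOUTS["TII_STD"]


def _tii(cls, group, subgroup, note, tail=9, layout=None, exemplar=None,
         **over):
    lay = layout if layout is not None else truncated(_TIIL, tail)
    _leaf("TypeII", cls, group, subgroup, lay, _merge(_TII, **over), note,
          exemplar)


_tii("1", "1a", "i", "short tail; Arg32 with Glu53", tail=4,
     pos={32: "R", 53: "E"})
_tii("1", "1a", "ii", "short tail; Arg32 with Lys53", tail=4,
     pos={32: "R", 53: "K"})
_tii("1", "1a", "iii", "short tail; Ala32 with Glu53", tail=4,
     pos={32: "A", 53: "E"})
_tii("1", "1a", "iv", "short tail; Ser32 with Gly53", tail=4,
     pos={32: "S", 53: "G"})
_tii("1", "1b", "", "Asn31, Trp33, Asn53, Tyr70", tail=4,
     pos={31: "N", 33: "W", 53: "N", 70: "Y"})
_tii("1", "1c", "", "short tail with further site substitutions", tail=4,
     pos={31: "E", 32: "G", 33: "L", 40: "L", 53: "R", 70: "V"})

_tii("2", "2a", "i", "six-residue tail; Arg32/Val40/Glu53", tail=6,
     pos={32: "R", 53: "E"})
_tii("2", "2a", "iia", "nine-residue tail; Ala32, Arg40, Lys53",
     pos={40: "R"})
_tii("2", "2a", "iib", "nine-residue tail; Arg32, Trp33, Glu53",
     pos={32: "R", 33: "W", 53: "E"})
_tii("2", "2a", "iic", "nine-residue tail; Gly31, Ser32, Met33, Leu40",
     pos={31: "G", 32: "S", 33: "M", 40: "L"})
_tii("2", "2a", "iiia", "seven-residue tail; Trp33, Lys40, Lys53", tail=7,
     pos={33: "W", 40: "K"})
_tii("2", "2a", "iiib", "seven-residue tail; Trp33, Lys40, Asn53", tail=7,
     pos={33: "W", 40: "K", 53: "N"})
_tii("2", "2a", "iiic", "seven-residue tail; Phe33, Arg40, Lys53", tail=7,
     pos={40: "R"})
_tii("2", "2a", "iv", "classical alpha-bungarotoxin: His33, Val40, "
     "terminal Gly", pos={33: "H"}, cterm_gly=True,
     exemplar="alpha-bungarotoxin")
_tii("2", "2a", "va", "eight-residue tail; Trp33 with Lys53", tail=8,
     pos={33: "W"})
_tii("2", "2a", "vb", "eight-residue tail; Trp33 with Glu53", tail=8,
     pos={33: "W", 53: "E"})
_tii("2", "2a", "vc", "eight-residue tail; Met37 with Phe33/Arg53", tail=8,
     pos={37: "M", 40: "R", 53: "R"})
_tii("2", "2a", "vd", "eight-residue tail; Met37 with Arg33/Lys53", tail=8,
     pos={33: "R", 37: "M", 40: "R"})
_tii("2", "2a", "via", "ten-residue tail; Ala32, Phe33, Val40", tail=10)
_tii("2", "2a", "vib", "ten-residue tail; Trp33 with Arg40", tail=10,
     pos={33: "W", 40: "R"})
_tii("2", "2a", "vic", "ten-residue tail; Tyr32, Trp33, Lys37", tail=10,
     pos={32: "Y", 33: "W", 37: "K", 40: "R"})
_tii("2", "2a", "vid", "ten-residue tail; His33 with Arg40", tail=10,
     pos={33: "H", 40: "R"})
_tii("2", "2a", "vii", "alpha-bungarotoxin-like site, distinct tail", tail=8,
     pos={33: "H"})
_tii("2", "2a", "viii", "Ala31, Asp32, Trp33", tail=10,
     pos={31: "A", 32: "D", 33: "W"})

_tii("2", "2b", "i", "non-His/Phe70: Tyr70, amidation candidates", tail=8,
     pos={32: "G", 40: "R", 70: "Y"}, cterm_gly=True)
_tii("2", "2b", "ii", "non-His/Phe70: Val70", tail=8,
     pos={32: "G", 40: "R", 70: "V"})
_tii("2", "2b", "iii", "non-His/Phe70: Pro70", tail=8,
     pos={32: "G", 40: "R", 70: "P"})

_tii("2", "2c", "i", "Phe70; seven-residue tail, Gly32 with Arg27", tail=7,
     pos={27: "R", 32: "G", 70: "F"})
_tii("2", "2c", "iia", "Phe70; Gly32 with Lys27", tail=7,
     pos={32: "G", 70: "F"})
_tii("2", "2c", "iib", "Phe70; Gly32 with Glu27", tail=7,
     pos={27: "E", 32: "G", 70: "F"})
_tii("2", "2c", "iiia", "Phe70; Ala32, Glu27, Asn53", tail=7,
     pos={27: "E", 53: "N", 70: "F"})
_tii("2", "2c", "iiib", "Phe70; Val32 with Lys27/Lys53", tail=7,
     pos={32: "V", 70: "F"})
_tii("2", "2c", "iva", "Phe70 with Arg40 and His33; Ala32",
     pos={33: "H", 40: "R", 70: "F"})
_tii("2", "2c", "ivb", "Phe70 with Arg40 and His33; Val32",
     pos={32: "V", 33: "H", 40: "R", 70: "F"})
_tii("2", "2c", "v", "Phe70; Glu27, Arg33, Leu37",
     pos={27: "E", 33: "R", 37: "L", 70: "F"})
_tii("2", "2c", "via", "alpha-cobratoxin: Ala32, Phe33, Arg40, Phe70",
     pos={40: "R", 70: "F"}, exemplar="alpha-cobratoxin")
_tii("2", "2c", "vib", "alpha-cobratoxin-like with Gly32",
     pos={32: "G", 40: "R", 70: "F"})
_tii("2", "2c", "vic", "alpha-cobratoxin-like with Asn32",
     pos={32: "N", 40: "R", 70: "F"})
_tii("2", "2c", "viia", "eight-residue tail; Lys27, Gly32, Phe33", tail=8,
     pos={32: "G", 70: "F"})
_tii("2", "2c", "viib", "eight-residue tail; Glu27, Ala32, Trp33", tail=8,
     pos={27: "E", 33: "W", 70: "F"})
_tii("2", "2c", "viiia", "ten-residue tail; Lys27, Gly32, Phe33", tail=10,
     pos={32: "G", 70: "F"})
_tii("2", "2c", "viiib", "ten-residue tail; Glu27, Ala32, Trp33", tail=10,
     pos={27: "E", 33: "W", 70: "F"})
_tii("2", "2c", "ix", "eleven-residue tail; Gly32, Arg33, Leu37", tail=11,
     pos={32: "G", 33: "R", 37: "L", 40: "R", 70: "F"})
_tii("2", "2c", "xa", "eleven-residue tail; Ala32, Phe33, Val40", tail=11,
     pos={70: "F"})
_tii("2", "2c", "xb", "eleven-residue tail; Ser32 variant", tail=11,
     pos={32: "S", 70: "F"})
_tii("2", "2c", "xi", "thirteen-residue tail; no alpha-7 binding reported",
     tail=13, pos={70: "F"})
_tii("2", "2c", "xii", "ten-residue tail; Val31 and Pro53", tail=10,
     pos={31: "V", 53: "P", 70: "F"})
_tii("2", "2c", "xiii", "loop II deletions around the tip; Gly31",
     layout=ALL_LAYOUTS["TII_X13"],
     pos={31: "G", 38: "-", 39: "-", 70: "F"})

_tii("3", "3a", "", "seventeen-residue tail; Arg33 with Leu37", tail=17,
     pos={33: "R", 37: "L", 40: "R", 70: "F"})
_tii("3", "3b", "", "long tail; aromatic Trp33 with Arg37", tail=20,
     pos={33: "W", 70: "F"})
_tii("3", "3c", "i", "drysdalin-like: Arg33, Leu37, Ala40", tail=22,
     pos={33: "R", 37: "L", 40: "A", 70: "F"}, exemplar="drysdalin")
_tii("3", "3c", "ii", "long tail with Gly31, Leu33, Glu53", tail=22,
     pos={31: "G", 33: "L", 53: "E", 70: "F"})

_tii("4", "", "", "kappa-neurotoxins: non-covalent dimers, short tail, "
     "Gln29, Arg53", tail=2,
     pos={29: "Q", 53: "R", 70: "-"}, dimer={"kappa": 0.8},
     exemplar="kappa-bungarotoxin")
_tii("5", "", "", "DPP2d-like non-covalent dimers, amidation candidate",
     pos={33: "W", 70: "F"}, cterm_gly=True, dimer={"dpp2d": 0.8},
     exemplar="DPP2d")
_tii("6", "6a", "", "covalent homodimer of alpha-cobratoxin chains",
     pos={40: "R", 70: "F"}, covalent=True)
_tii("6", "6b", "", "covalent heterodimer partner chain (cytotoxin-like "
     "site loss)", pos={27: "L", 31: "K", 33: "L", 37: "M"}, covalent=True)

# ===========================================================================
# Type III: 3 subgroups
# ===========================================================================

_TIII = {"ncys": 8, "fifth": "none", "cterm_gly": False, "proflanks": (),
         "pos": {}}

_leaf("TypeIII", "1", "1a", "", ALL_LAYOUTS["TIII_1A"],
      _merge(_TIII, pos={37: "G"}),
      "58 residues with the loop II Gly37")
_leaf("TypeIII", "1", "1b", "", ALL_LAYOUTS["TIII_1B"],
      _merge(_TIII, pos={37: "-"}),
      "57 residues, Gly37 absent")
_leaf("TypeIII", "2", "", "", ALL_LAYOUTS["TIII_2"],
      _merge(_TIII, pos={37: "G", 71: "Y"}),
      "extended tail carrying an aromatic Tyr71")

# ===========================================================================
# Non-conventional: 20 subgroups
# ===========================================================================

_NC = {"ncys": 10, "fifth": "1", "cterm_gly": False, "proflanks": (),
       "pos": {}}


def _nc(cls, group, subgroup, note, layout, exemplar=None, **over):
    _leaf("NonConventional", cls, group, subgroup, layout,
          _merge(_NC, **over), note, exemplar)


_NC1 = LAYOUTS["NC1"]
_nc("1", "1a", "", "candoxin-like: Glu29, Trp31, Glu33, Arg39, Arg42, "
    "Glu44; Ser55", _NC1,
    pos={29: "E", 31: "W", 33: "E", 34: "A", 38: "-", 39: "R", 42: "R",
         44: "E", 55: "S"}, exemplar="candoxin")
_nc("1", "1b", "", "Thr33 replacing the acidic Glu33", _NC1,
    pos={29: "E", 31: "W", 33: "T", 34: "A", 38: "-", 39: "R", 42: "R",
         44: "E", 55: "S"})
_nc("1", "1c", "", "His38 variant with Lys55", ALL_LAYOUTS["NC1C"],
    pos={29: "A", 31: "W", 33: "E", 34: "-", 38: "H", 39: "R", 42: "R",
         44: "E", 55: "K"})
_nc("2", "", "", "gamma-bungarotoxin-like: loop II RGD, Arg29, Trp31",
    LAYOUTS["NC2"],
    pos={29: "R", 31: "W", 55: "K"}, **{"motif+": ("RGD",)},
    exemplar="gamma-bungarotoxin")

_NC3 = LAYOUTS["NC3"]

_nc("3", "3a", "i", "WTX-like: Trp41 with Lys29/His31/Arg33/Arg37", _NC3,
    pos={29: "K", 31: "H", 33: "R", 37: "R", 41: "W", 42: "R", 55: "K"},
    exemplar="WTX")
_nc("3", "3a", "ii", "Trp41; Arg29/Tyr31 with Lys33/Asn37", _NC3,
    pos={29: "R", 31: "Y", 33: "K", 37: "N", 41: "W", 42: "R", 55: "K"})
_nc("3", "3a", "iii", "Trp41; Arg29/Tyr31 with Glu33/Lys37", _NC3,
    pos={29: "R", 31: "Y", 33: "E", 37: "K", 41: "W", 42: "R", 55: "K"})
_nc("3", "3b", "i", "Leu41 with the basic loop II pair", _NC3,
    pos={29: "K", 31: "H", 33: "R", 37: "R", 41: "L", 42: "R", 55: "K"})
_nc("3", "3b", "ii", "Leu41; His31 to Gln31", _NC3,
    pos={29: "K", 31: "Q", 33: "R", 37: "R", 41: "L", 42: "R", 55: "K"})
_nc("3", "3b", "iii", "Leu41; Met29 and Gln31", _NC3,
    pos={29: "M", 31: "Q", 33: "R", 37: "R", 41: "L", 42: "R", 55: "K"})
_nc("3", "3c", "i", "Lys41; Gly33/Lys37 with Lys42", _NC3,
    pos={29: "R", 31: "Y", 33: "G", 37: "K", 41: "K", 42: "K", 55: "K"})
_nc("3", "3c", "ii", "Lys41; Asn37 with Arg42", _NC3,
    pos={29: "R", 31: "Y", 33: "G", 37: "N", 41: "K", 42: "R", 55: "K"})
_nc("3", "3c", "iii", "Lys41; Gln42 with an extra Cys40", _NC3,
    ncys=11, xcys=(40,),
    pos={29: "R", 31: "Y", 33: "G", 37: "K", 41: "K", 42: "Q", 55: "K"})
_nc("3", "3c", "iv", "Lys41; Gln42 with Gly29", _NC3,
    pos={29: "G", 31: "Y", 33: "G", 37: "K", 41: "K", 42: "Q", 55: "K"})
_nc("3", "3c", "v", "Lys41; Tyr31 and Lys37 deleted", ALL_LAYOUTS["NC3V"],
    pos={29: "R", 31: "-", 33: "R", 37: "-", 41: "K", 42: "R", 55: "K"})
_nc("3", "3d", "i", "Lys41 with acidic Asp31; Arg42", _NC3,
    pos={29: "K", 31: "D", 33: "R", 37: "R", 41: "K", 42: "R", 55: "K"})
_nc("3", "3d", "ii", "Lys41, Asp31 with Lys42", _NC3,
    pos={29: "K", 31: "D", 33: "R", 37: "R", 41: "K", 42: "K", 55: "K"})
_nc("3", "3d", "iii", "Lys41 with uncharged Asn31", _NC3,
    pos={29: "K", 31: "N", 33: "R", 37: "R", 41: "K", 42: "R", 55: "K"})
_nc("3", "3d", "iv", "Lys41; Gly42 with Gln55", _NC3,
    pos={29: "K", 31: "D", 33: "R", 37: "R", 41: "K", 42: "G", 55: "Q"})
_nc("4", "", "", "long-loop class (BM8/BM14-like); Glu40/Ala41",
    LAYOUTS["NC4"], pos={40: "E", 41: "A"})

# ===========================================================================
# Omega: 5 subgroups
# ===========================================================================

_OM = {"ncys": 8, "fifth": "none", "cterm_gly": False, "proflanks": (),
       "pos": {7: "H", 27: "K", 28: "T", 29: "T", 30: "M", 31: "F",
               32: "F", 38: "H", 53: "K", 54: "Y"}}


def _om(cls, group, note, exemplar=None, **over):
    _leaf("Omega", cls, group, "", LAYOUTS["OM"], _merge(_OM, **over),
          note, exemplar)


_om("1", "1a", "Oh9-1-like: complete functional site", exemplar="Oh9-1")
_om("1", "1b", "Lys27 and Lys53 to Arg", pos={27: "R", 53: "R"})
_om("1", "1c", "Thr29 to Val and Tyr54 to Asn (gain-of-affinity sites)",
    pos={29: "V", 54: "N"})
_om("1", "1d", "multiple loop I/II changes", pos={7: "N", 28: "S", 30: "L"})
_om("2", "", "nakaroxin-like divergent site", pos={32: "Y", 38: "N"},
    exemplar="nakaroxin")

# ===========================================================================
# Sigma: 7 subgroups
# ===========================================================================

_SG = {"ncys": 8, "fifth": "none", "proflanks": (),
       "pos": {21: "E", 30: "G", 33: "H", 42: "I", 44: "T"}}


def _sg(cls, group, note, tail, exemplar=None, **over):
    _leaf("Sigma", cls, group, "", truncated(LAYOUTS["SG"], tail),
          _merge(_SG, **over), note, exemplar)


_sg("1", "1a", "fulditoxin-like: Zn-binding His33, dimer interface, "
    "terminal Gly", 5, cterm_gly=True, dimer={"sigma": 0.9},
    exemplar="fulditoxin")
_sg("1", "1b", "Zn-site His33 to Pro; Glu21 to Lys", 5, cterm_gly=True,
    pos={33: "P", 21: "K"}, dimer={"sigma": 0.5})
_sg("1", "1c", "His33 to Arg with interface substitutions", 5,
    cterm_gly=True, pos={33: "R", 21: "K", 30: "P", 42: "S", 44: "Q"},
    dimer={"sigma": 0.5})
_sg("2", "2a", "shortest tail; interface and Zn-His conserved", 2,
    cterm_gly=False, dimer={"sigma": 0.9})
_sg("2", "2b", "short tail; His33 to Pro", 2, cterm_gly=False,
    pos={33: "P"}, dimer={"sigma": 0.5})
_sg("2", "2c", "short tail; His33 to Gln", 2, cterm_gly=False,
    pos={33: "Q"}, dimer={"sigma": 0.5})
_sg("3", "", "two-residue tail extension over class 2", 4,
    cterm_gly=False, dimer={"sigma": 0.9})

# ===========================================================================
# Colubrid: 31 subgroups
# ===========================================================================

_CO = {"ncys": 11, "fifth": "1", "cterm_gly": False, "proflanks": (50, 54),
       "pos": {}, "motif+": ("CYTLY", "WAVK")}


def _co(cls, group, subgroup, note, ext, tail=2, exemplar=None,
        precursor=None, **over):
    short = over.pop("short_loop2", False)
    lay = colubrid_layout(ext, tail, short_loop2=short)
    atoms = _merge(_CO, next=ext, **over)
    _leaf("Colubrid", cls, group, subgroup, lay, atoms, note, exemplar,
          precursor)


# -- class 1: pyroGlu N-terminus, seven-residue extension --
for sub, r27 in (("i", "K"), ("ii", "R"), ("iii", "T")):
    _co("1", "1a", sub,
        f"Xaa-Gln processing, pyroGlu start; loop II {r27}27",
        ext=7, procsite="XaaGln", nterm_gln=True, pos={27: r27},
        exemplar="denmotoxin" if sub == "i" else None,
        precursor={"kind": "XaaGln", "prop": 15})
_co("1", "1b", "", "tetrabasic (back-to-back dibasic) site; WTVK loop II, "
    "four residues shorter", ext=7, procsite="tetrabasic", nterm_gln=True,
    short_loop2=True, precursor={"kind": "tetrabasic", "prop": 15},
    exemplar="sulmotoxin 1",
    **{"motif+": ("CYTLY", "WTVK"), "motif-": ("WAVK",)})
_co("1", "1c", "", "dibasic processing; seven-residue extension", ext=7,
    procsite="dibasic", procmotif="KR", nterm_gln=True,
    precursor={"kind": "dibasic", "motif": "KR", "prop": 15})
_co("1", "1d", "", "dibasic processing; seventeen-residue extension",
    ext=17, procsite="dibasic", procmotif="KR", nterm_gln=True,
    precursor={"kind": "dibasic", "motif": "KR", "prop": 15})
_co("1", "1e", "", "monobasic processing; six-residue extension", ext=6,
    procsite="monobasic", nterm_gln=True,
    precursor={"kind": "monobasic", "motif": "K", "prop": 15})
_co("1", "1f", "", "alpha-colubritoxin: propeptide/processing unknown",
    ext=7, procsite="none", nterm_gln=True, exemplar="alpha-colubritoxin")

# -- classes 2-7: Pro or short N-termini --
_co("2", "", "", "RRKKK pentabasic site; mature N-terminal Pro", ext=5,
    procsite="pentabasic_RRKKK", nterm_gln=False,
    precursor={"kind": "pentabasic", "motif": "RRKKK", "prop": 8})
_co("3", "", "", "KKK tribasic site", ext=7, procsite="tribasic_KKK",
    nterm_gln=False, precursor={"kind": "tribasic", "motif": "KKK",
                                "prop": 8})
_co("4", "", "", "dibasic RR/KR site; six-residue extension", ext=6,
    procsite="dibasic", procmotif=("RR", "KR"), nterm_gln=False,
    precursor={"kind": "dibasic", "motif": "KR", "prop": 7})
_co("5", "", "", "dibasic RK site; seven-residue extension", ext=7,
    procsite="dibasic", procmotif="RK", nterm_gln=False,
    precursor={"kind": "dibasic", "motif": "RK", "prop": 8})
_co("6", "", "", "monobasic site; six-residue extension", ext=6,
    procsite="monobasic", nterm_gln=False,
    precursor={"kind": "monobasic", "motif": "K", "prop": 7})
_co("7", "", "", "no propeptide (exon 2 absent); short extension", ext=3,
    procsite="none", nterm_gln=False)

# -- classes 8-9: covalent heterodimer subunits --
for sub, r27 in (("i", "K"), ("ii", "R"), ("iii", "T")):
    _co("8", "8a", sub,
        f"subunit A: interchain Cys in loop II; Xaa-Gln processing ({r27}27)",
        ext=7, ncys=12, xcys=(36,), procsite="XaaGln", nterm_gln=True,
        pos={27: r27, 36: "C"}, precursor={"kind": "XaaGln", "prop": 15},
        exemplar="irditoxin A" if sub == "i" else None)
_co("8", "8a", "iv", "subunit A with a five-residue C-tail extension",
    ext=7, tail=7, ncys=12, xcys=(36,), procsite="XaaGln", nterm_gln=True,
    pos={27: "K", 36: "C"}, precursor={"kind": "XaaGln", "prop": 15})
_co("8", "8a", "v", "subunit A with a seven-residue C-tail extension",
    ext=7, tail=9, ncys=12, xcys=(36,), procsite="XaaGln", nterm_gln=True,
    pos={27: "K", 36: "C", 53: "K"},
    precursor={"kind": "XaaGln", "prop": 15})
_co("8", "8a", "vi", "subunit A tail extension with loop III Arg53",
    ext=7, tail=9, ncys=12, xcys=(36,), procsite="XaaGln", nterm_gln=True,
    pos={27: "K", 36: "C", 53: "R"},
    precursor={"kind": "XaaGln", "prop": 15})
_co("8", "8b", "", "subunit A with dibasic processing", ext=7, ncys=12,
    xcys=(36,), procsite="dibasic", procmotif="KR", nterm_gln=True,
    pos={36: "C"}, precursor={"kind": "dibasic", "motif": "KR", "prop": 15})
_co("8", "8c", "", "subunit A without a propeptide", ext=3, ncys=12,
    xcys=(36,), procsite="none", nterm_gln=False, pos={36: "C"})

_co("9", "9a", "", "subunit B: interchain Cys in loop I; Xaa-Gln "
    "processing", ext=7, ncys=12, xcys=(7,), procsite="XaaGln",
    nterm_gln=True, pos={7: "C"}, precursor={"kind": "XaaGln", "prop": 15},
    exemplar="irditoxin B")
_co("9", "9b", "", "subunit B with RR dibasic processing", ext=7, ncys=12,
    xcys=(7,), procsite="dibasic", procmotif="RR", nterm_gln=False,
    pos={7: "C"}, precursor={"kind": "dibasic", "motif": "RR", "prop": 15})
_co("9", "9c", "", "subunit B with KR dibasic processing", ext=7, ncys=12,
    xcys=(7,), procsite="dibasic", procmotif="KR", nterm_gln=False,
    pos={7: "C"}, precursor={"kind": "dibasic", "motif": "KR", "prop": 15})
_co("9", "9d", "", "subunit B with monobasic processing", ext=6, ncys=12,
    xcys=(7,), procsite="monobasic", nterm_gln=False, pos={7: "C"},
    precursor={"kind": "monobasic", "motif": "K", "prop": 15})
_co("9", "9e", "", "subunit B with a C-terminal extension", ext=7, tail=7,
    ncys=12, xcys=(7,), procsite="XaaGln", nterm_gln=True, pos={7: "C"},
    precursor={"kind": "XaaGln", "prop": 15})

_co("10", "10a", "", "interchain Cys in both loop I and loop II; Lys53",
    ext=7, ncys=13, xcys=(7, 36), procsite="XaaGln", nterm_gln=True,
    pos={7: "C", 36: "C", 53: "K"}, precursor={"kind": "XaaGln", "prop": 15})
_co("10", "10b", "", "both interchain Cys with loop III Arg53", ext=7,
    ncys=13, xcys=(7, 36), procsite="XaaGln", nterm_gln=True,
    pos={7: "C", 36: "C", 53: "R"}, precursor={"kind": "XaaGln", "prop": 15})

_co("11", "a", "", "two conserved Cys missing; CYTLY retained", ext=3,
    ncys=9, anchors=6, procsite="none", nterm_gln=False,
    pos={61: "S", 66: "S"}, skip_ctail=True,
    **{"motif+": ("CYTLY",), "motif-": ()})
_co("11", "b", "", "two conserved Cys missing; CYTLY replaced by CGGHL",
    ext=3, ncys=9, anchors=6, procsite="none", nterm_gln=False,
    pos={61: "S", 66: "S"}, skip_ctail=True,
    **{"motif+": ("CGGHL",), "motif-": ("CYTLY", "WAVK")})


# ===========================================================================
# derived tables
# ===========================================================================

def leaf_by_path(path: str) -> LeafSpec:
    for leaf in LEAVES:
        if leaf.path == path:
            return leaf
    raise KeyError(path)


FAMILY_TOTALS = {"TypeI": 36, "TypeII": 56, "TypeIII": 3,
                 "NonConventional": 20, "Omega": 5, "Sigma": 7,
                 "Colubrid": 31}


def render_registry_tsv() -> str:
    rows = ["path\tpredicate\tspecificity\tprovenance\texemplar"]
    for leaf in LEAVES:
        pred = leaf.clauses()
        rows.append("\t".join([
            leaf.path, pred.render(), str(pred.specificity), leaf.note,
            leaf.exemplar or ""]))
    return "\n".join(rows) + "\n"
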