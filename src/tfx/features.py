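"""Classifier-visible features of an aligned toxin.

Everything the registry predicates can reference is computed here: cysteine
topology, loop lengths, residues at criteria columns, flanking prolines,
loop II motifs, terminal flags, dimer-interface conservation and (for
colubrid precursors) the processing annotation.  Feature extraction is a
pure function of (sequence, frame): repeated calls are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .frame import AlignedToxin, LoopPartition, partition_loops
from .layouts import (CYS_ANCHOR_COLS, FLANK_COLS, LOOP1_EXTRA_CYS,
                      LOOP2_EXTRA_CYS)
from .records import ToxinRecord

# residue-class compatibility groups used by conservative-substitution rules:
# His can stand in for Phe in stacking, Arg for an aromatic via pi-cation, etc.
RESIDUE_CLASSES = {
    "aromatic": set("FWYH"),
    "positive": set("KR"),
    "negative": set("DE"),
    "small": set("GSA"),
    "hydrophobic": set("LIVMFW"),
}


def same_class(a: str, b: str) -> bool:
    if a == b:
        return True
    return any(a in grp and b in grp for grp in RESIDUE_CLASSES.values())


#: loop II motif inventory (exact matches; WAVK variants included)
MOTIFS = ("CYTLY", "CGGHL", "WAVK", "WTVK", "WSVK", "WVVK", "RGD")

#: dimer-interface models: frame column -> expected residue.  The sigma set
#: is figure-derived (low confidence); the kappa Leu is curated at column 58
#: because the published interface numbering collides with the Cys#6 column.
DIMER_MODELS: dict[str, dict[int, str]] = {
    "haditoxin": {7: "Q", 8: "S", 23: "F", 42: "E", 54: "L"},
    "kappa": {27: "K", 37: "R", 52: "F", 53: "R", 58: "L"},
    "sigma": {26: "I", 29: "L", 31: "F", 33: "H", 34: "I", 44: "T"},
    "dpp2d": {33: "W", 58: "E", 59: "K"},
}

#: curated functional-site table: model -> (column -> (residue, role)).
#: roles: core residues form the shared binding core; the rest are variant.
FUNCTIONAL_SITES: dict[str, dict[int, tuple[str, str]]] = {
    "erabutoxin_a": {7: ("Q", "variant"), 8: ("S", "variant"),
                     10: ("Q", "variant"), 27: ("K", "core"),
                     29: ("W", "core"), 31: ("D", "variant"),
                     36: ("F", "variant"), 37: ("R", "core"),
                     42: ("E", "variant"), 53: ("K", "core")},
    "alpha-cobratoxin/torpedo": {27: ("K", "core"), 29: ("W", "core"),
                                 31: ("D", "core"), 33: ("F", "variant"),
                                 37: ("R", "core"), 40: ("R", "variant"),
                                 53: ("K", "core"), 70: ("F", "variant")},
    "alpha-cobratoxin/alpha7": {29: ("W", "core"), 31: ("D", "core"),
                                32: ("A", "variant"), 33: ("F", "variant"),
                                37: ("R", "core"), 39: ("K", "variant"),
                                40: ("R", "variant"), 70: ("F", "variant")},
    "WTX": {29: ("K", "variant"), 31: ("H", "variant"), 33: ("R", "core"),
            37: ("R", "core"), 41: ("W", "variant"), 42: ("R", "variant"),
            55: ("K", "variant")},
    "Oh9-1/muscle": {7: ("H", "core"), 27: ("K", "core"), 28: ("T", "variant"),
                     29: ("T", "variant"), 30: ("M", "core"),
                     31: ("F", "variant"), 32: ("F", "core"),
                     38: ("H", "core"), 53: ("K", "core")},
    "Oh9-1/alpha3beta2": {7: ("H", "core"), 27: ("K", "core"),
                          30: ("M", "core"), 32: ("F", "core"),
                          38: ("H", "core"), 53: ("K", "core")},
}


@dataclass
class CysProfile:
    n_cys: int
    anchor_matched: int
    extra_cys_cols: tuple[int, ...]
    unaligned_cys: int
    free_thiol_candidates: tuple[int, ...]   # heuristic; always "inferred"
    intersubunit_capable: bool


def cys_profile(aligned: AlignedToxin) -> CysProfile:
    seq = aligned.record.residues
    n_cys = seq.count("C")
    anchor_matched = aligned.anchors_matched
    extra = tuple(sorted(c for c, r in aligned.res_at.items()
                         if r == "C" and c not in CYS_ANCHOR_COLS))
    unaligned = n_cys - anchor_matched - len(extra)
    paired = set()
    if all(c in extra for c in LOOP1_EXTRA_CYS):
        paired.update(LOOP1_EXTRA_CYS)
    if all(c in extra for c in LOOP2_EXTRA_CYS):
        paired.update(LOOP2_EXTRA_CYS)
    free = tuple(c for c in extra if c not in paired)
    inter = any(4 <= c <= 44 for c in free)
    return CysProfile(n_cys, anchor_matched, extra, unaligned, free, inter)


def flanking_prolines(aligned: AlignedToxin,
                      site_cols=FLANK_COLS) -> set[int]:
    """Frame columns among the loop I/III flank positions occupied by Pro."""
    return {c for c in site_cols if aligned.res_at.get(c) == "P"}


def motif_scan(record: ToxinRecord,
               loops: LoopPartition | None) -> list[tuple[str, str, tuple[int, int]]]:
    """All exact motif hits with their region; overlapping hits included.

    Returns (motif, region, (start, stop)) with 1-based half-open original
    positions; region is 'loop2' when the hit lies strictly inside loop II.
    """
    seq = record.residues
    hits = []
    for motif in MOTIFS:
        start = seq.find(motif)
        while start != -1:
            iv = (start + 1, start + 1 + len(motif))
            region = "other"
            if loops is not None and loops.loop2 is not None:
                lo, hi = loops.loop2
                if lo <= iv[0] and iv[1] <= hi:
                    region = "loop2"
            hits.append((motif, region, iv))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h[2][0], h[0]))
    return hits


def terminal_flags(record: ToxinRecord) -> tuple[bool, bool]:
    """(cterm_gly, nterm_gln).  A terminal Gly is only an amidation
    *candidate* — some toxins carry it unamidated; an N-terminal Gln is a
    pyroglutamate candidate."""
    seq = record.residues
    return seq.endswith("G"), seq.startswith("Q")


def dimer_interface_score(aligned: AlignedToxin, model: str) -> float:
    """Fraction of a model's interface columns occupied by the model residue
    or a same-class residue."""
    try:
        cols = DIMER_MODELS[model]
    except KeyError:
        raise ValueError(f"unknown dimer model {model!r}") from None
    ok = sum(1 for col, res in cols.items()
             if (got := aligned.res_at.get(col)) is not None
             and same_class(got, res))
    return ok / len(cols)


@dataclass
class FeatureVector:
    """All classifier-visible features of one toxin."""

    record_id: str
    family: str                          # best-scoring alignment family
    cys: CysProfile
    loops: LoopPartition
    res_at: dict[int, str]
    pro_flanks: set[int]
    motifs: list
    cterm_gly: bool
    nterm_gln: bool
    dimer_scores: dict[str, float]
    nterm_ext: int | None
    covalent: bool
    propeptide: object | None = None     # PrecursorAnnotation when known
    flags: set[str] = field(default_factory=set)

    # --- DSL-facing accessors --------------------------------------------
    def site(self, col: int) -> str | None:
        res = self.res_at.get(col)
        if res == "X":
            return None
        if res is not None:
            return res
        if "anchor_incomplete" in self.flags:
            matched = [c for c in CYS_ANCHOR_COLS if self.res_at.get(c) == "C"]
            if not matched or col > max(matched):
                return None
        return "-"

    @property
    def ncys(self) -> int:
        return self.cys.n_cys

    @property
    def anchors_matched(self) -> int:
        return self.cys.anchor_matched

    @property
    def extra_cys_cols(self):
        return self.cys.extra_cys_cols

    @property
    def fifth_ss_loop(self) -> str:
        extra = set(self.cys.extra_cys_cols)
        if sum(1 for c in extra if 5 <= c <= 15) >= 2:
            return "1"
        if all(c in extra for c in LOOP2_EXTRA_CYS):
            return "2"
        return "none"

    @property
    def loop1len(self):
        return self.loops.length("loop1")

    @property
    def loop2len(self):
        return self.loops.length("loop2")

    @property
    def loop3len(self):
        return self.loops.length("loop3")

    @property
    def ctail_len(self):
        return self.loops.length("ctail")

    @property
    def procsite(self):
        return None if self.propeptide is None else self.propeptide.processing_site

    @property
    def procmotif(self):
        return None if self.propeptide is None else self.propeptide.site_motif


def extract_features(aligned: AlignedToxin,
                     propeptide=None) -> FeatureVector:
    """Compose the full feature vector; deterministic, never drops a flag."""
    loops = partition_loops(aligned)
    rec = aligned.record
    inv = {c: p for p, c in aligned.col_of.items()}
    ext = None
    if 1 in inv:
        ext = inv[1] - 1
    else:
        first_canonical = min((c for c in inv if c >= 1), default=None)
        if first_canonical is not None:
            ext = max(0, inv[first_canonical] - first_canonical)
    cterm_gly, nterm_gln = terminal_flags(rec)
    fv = FeatureVector(
        record_id=rec.id,
        family=aligned.family,
        cys=cys_profile(aligned),
        loops=loops,
        res_at=dict(aligned.res_at),
        pro_flanks=flanking_prolines(aligned),
        motifs=motif_scan(rec, loops),
        cterm_gly=cterm_gly,
        nterm_gln=nterm_gln,
        dimer_scores={m: dimer_interface_score(aligned, m)
                      for m in DIMER_MODELS},
        nterm_ext=ext,
        covalent=rec.metadata.get("covalent_dimer") == "1",
        propeptide=propeptide,
        flags=set(aligned.flags),
    )
    return fv


# ---------------------------------------------------------------------------
# renderers for the shipped annotation tables
# ---------------------------------------------------------------------------

def render_functional_sites_tsv() -> str:
    rows = ["model\tcolumn\tresidue\trole"]
    for model, cols in FUNCTIONAL_SITES.items():
        for col in sorted(cols):
            res, role = cols[col]
            rows.append(f"{model}\t{col}\t{res}\t{role}")
    return "\n".join(rows) + "\n"


def render_dimer_models_tsv() -> str:
    rows = ["model\tcolumn\tresidue\tconfidence"]
    for model, cols in DIMER_MODELS.items():
        conf = "figure-derived,low" if model == "sigma" else "curated"
        for col in sorted(cols):
            rows.append(f"{model}\t{col}\t{cols[col]}\t{conf}")
    return "\n".join(rows) + "\n"
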