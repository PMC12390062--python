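"""Colubrid propeptide detection and processing-site classification.

Colubrid three-finger toxins are expressed as precursors whose propeptide
(encoded by an extra exon) is removed during maturation, either at basic
residue runs (mono-/di-/tri-/tetra-/pentabasic, furin-style) or by cleavage
of an Xaa-Gln bond whose newly exposed Gln cyclises to pyroglutamate.
Cleavage is taken C-terminal to the basic run and N-terminal to the Gln;
the mature-start position is exposed so callers can override either
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ToxinRecord

#: the propeptide search window after signal removal — published propeptides
#: are 7–15 residues, so this keeps internal dibasic pairs out of reach
SEARCH_WINDOW = 25

SITE_TYPES = ("pentabasic_RRKKK", "tetrabasic", "tribasic_KKK", "dibasic",
              "monobasic", "XaaGln", "none")


@dataclass
class PrecursorAnnotation:
    propeptide: tuple[int, int] | None   # 1-based inclusive interval
    processing_site: str
    site_motif: str
    mature_start: int
    nterm_ext_len: int | None            # filled after alignment
    pyroglu_candidate: bool
    exon2_class: str

    @property
    def propeptide_len(self) -> int:
        return 0 if self.propeptide is None \
            else self.propeptide[1] - self.propeptide[0] + 1


def _basic_runs(seq: str, window: int):
    """Maximal K/R runs starting within the window, longest first."""
    runs = []
    i = 0
    while i < min(len(seq), window):
        if seq[i] in "KR":
            j = i
            while j < len(seq) and seq[j] in "KR":
                j += 1
            runs.append((i, j))       # [i, j) 0-based
            i = j
        else:
            i += 1
    return runs


def _xaa_gln(seq: str, window: int):
    """First Gln that plausibly starts a three-finger mature region."""
    for i in range(1, min(len(seq), window)):
        if seq[i] == "C":        # propeptides carry no cysteine
            return None
        if seq[i] == "Q":
            downstream = seq[i:]
            first_c = downstream.find("C")
            if downstream.count("C") >= 8 and 0 <= first_c <= 11:
                return i
    return None


def detect_processing_site(record: ToxinRecord) -> PrecursorAnnotation:
    """Classify the propeptide processing site of a signal-less precursor.

    The highest-priority hit wins: pentabasic RRKKK, tetrabasic, tribasic
    KKK, dibasic, monobasic, then Xaa-Gln.  Exactly one site class is
    returned; with no site the input is taken as already mature.
    """
    if record.form != "precursor_signal_removed":
        raise ValueError("processing detection requires a precursor with the "
                         "signal peptide removed (form=precursor_signal_removed)")
    seq = record.residues
    runs = _basic_runs(seq, SEARCH_WINDOW)
    # propeptides carry no cysteine: a basic run inside the disulfide core
    # is not a processing site
    first_c = seq.find("C")
    if first_c != -1:
        runs = [r for r in runs if r[1] <= first_c]

    site = motif = None
    cut = None                          # 0-based index of mature start
    if runs:
        # prefer the longest run; leftmost on ties
        i, j = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        run = seq[i:j]
        n = len(run)
        if n >= 5 and run[-5:] == "RRKKK":
            site, motif, cut = "pentabasic_RRKKK", "RRKKK", j
        elif n >= 4:
            site, motif, cut = "tetrabasic", run[-4:], j
        elif n == 3 and run == "KKK":
            site, motif, cut = "tribasic_KKK", "KKK", j
        elif n >= 2:
            site, motif, cut = "dibasic", run[-2:], j
        else:
            site, motif, cut = "monobasic", run, j
    if site is None:
        q = _xaa_gln(seq, SEARCH_WINDOW)
        if q is not None:
            site, motif, cut = "XaaGln", seq[q - 1] + "Q", q

    if site is None:
        return PrecursorAnnotation(
            propeptide=None, processing_site="none", site_motif="",
            mature_start=1, nterm_ext_len=None, pyroglu_candidate=False,
            exon2_class="absent")

    mature_start = cut + 1
    pyroglu = seq[cut] == "Q"
    prop_len = cut
    exon2 = f"{motif or site}/{prop_len}" if site != "XaaGln" \
        else f"pyroGln/{prop_len}"
    return PrecursorAnnotation(
        propeptide=(1, cut), processing_site=site, site_motif=motif,
        mature_start=mature_start, nterm_ext_len=None,
        pyroglu_candidate=pyroglu, exon2_class=exon2)


def mature_record(record: ToxinRecord,
                  ann: PrecursorAnnotation | None = None) -> tuple[ToxinRecord, PrecursorAnnotation]:
    """Derive the mature-form record from a signal-less precursor."""
    if ann is None:
        ann = detect_processing_site(record)
    seq = record.residues[ann.mature_start - 1:]
    meta = dict(record.metadata)
    meta["processing_site"] = ann.processing_site
    rec = ToxinRecord(id=record.id, residues=seq,
                      description=record.description, form="mature",
                      metadata=meta)
    return rec, ann


def nterm_extension(aligned) -> int | None:
    """Residues preceding the canonical three-finger start (frame column 1).

    Canonical elapid toxins give 0; colubrid classes give their published
    extensions.  Unknown for anchor-incomplete alignments without a mapped
    canonical start.
    """
    inv = {c: p for p, c in aligned.col_of.items()}
    if 1 in inv:
        return inv[1] - 1
    if "anchor_incomplete" in aligned.flags:
        return None
    first = min((c for c in inv if c >= 1), default=None)
    if first is None:
        return None
    return max(0, inv[first] - first)
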