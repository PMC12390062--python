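"""Per-column conservation profiling over a set of aligned toxins.

Percentages use the non-gap occupancy of a column as the denominator, so a
deletion never reads as a substitution; conservative (same residue class)
agreement is reported alongside strict identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FUNCTIONAL_SITES, same_class
from .layouts import MAX_COL, MIN_COL


@dataclass
class ColumnConservation:
    column: int
    canonical: str | None
    counts: dict[str, int]
    gaps: int

    @property
    def occupancy(self) -> int:
        return sum(self.counts.values())

    @property
    def conservation_pct(self) -> float | None:
        occ = self.occupancy
        if occ == 0 or self.canonical is None:
            return None
        return 100.0 * self.counts.get(self.canonical, 0) / occ

    @property
    def conservative_pct(self) -> float | None:
        occ = self.occupancy
        if occ == 0 or self.canonical is None:
            return None
        ok = sum(n for r, n in self.counts.items()
                 if same_class(r, self.canonical))
        return 100.0 * ok / occ

    @property
    def substitutions(self) -> list[tuple[str, int]]:
        subs = [(r, n) for r, n in self.counts.items() if r != self.canonical]
        return sorted(subs, key=lambda t: (-t[1], t[0]))


@dataclass
class ConservationProfile:
    n_sequences: int
    columns: dict[int, ColumnConservation]


def column_conservation(aligned_set, columns,
                        canonical: dict[int, str] | None = None
                        ) -> ConservationProfile:
    """Exact residue tallies and conservation percentages per column.

    ``canonical`` defaults to the curated functional-site residues where a
    column is covered by one of the site models.
    """
    aligned_set = list(aligned_set)
    if not aligned_set:
        raise ValueError("need at least one aligned toxin")
    if canonical is None:
        canonical = {}
        for model in FUNCTIONAL_SITES.values():
            for col, (res, _) in model.items():
                canonical.setdefault(col, res)
    out = {}
    for col in columns:
        if not MIN_COL <= col <= MAX_COL:
            raise ValueError(f"column {col} outside frame")
        counts: dict[str, int] = {}
        gaps = 0
        for a in aligned_set:
            res = a.res_at.get(col)
            if res is None:
                gaps += 1
            else:
                counts[res] = counts.get(res, 0) + 1
        out[col] = ColumnConservation(col, canonical.get(col), counts, gaps)
    return ConservationProfile(len(aligned_set), out)


def core_report(profile: ConservationProfile,
                model: str = "erabutoxin_a") -> str:
    """Format core vs variant site conservation; pure formatting, no
    recomputation."""
    sites = FUNCTIONAL_SITES[model]
    lines = [f"conservation over {profile.n_sequences} sequences "
             f"(site model: {model})"]
    for role in ("core", "variant"):
        cols = [c for c, (_, r) in sorted(sites.items()) if r == role
                and c in profile.columns]
        if not cols:
            continue
        lines.append(f"[{role} sites]")
        for col in cols:
            cc = profile.columns[col]
            pct = cc.conservation_pct
            pct_s = "n/a" if pct is None else f"{pct:.1f}%"
            subs = ", ".join(f"{r}:{n}" for r, n in cc.substitutions[:5])
            lines.append(f"  col {col} ({cc.canonical}): {pct_s}"
                         + (f"; substitutions {subs}" if subs else ""))
    return "\n".join(lines)
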