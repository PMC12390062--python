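"""The conjunctive criteria DSL used by the taxonomy registry.

Predicates are conjunctions of atomic clauses; disjunction exists only as a
residue/value set inside one atom.  Evaluation is three-valued: a clause
whose underlying feature is unknown (an X residue at the column, a missing
anchor that leaves a loop length undefined, absent precursor information)
evaluates to ``None`` — it never silently passes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class DSLError(ValueError):
    """Syntax error in a predicate, with clause location."""


def _fmt_set(vals) -> str:
    return "{" + ",".join(str(v) for v in sorted(vals)) + "}"


@dataclass(frozen=True)
class Clause:
    kind: str
    arg: object = None
    value: object = None

    # ---- rendering -------------------------------------------------------
    def render(self) -> str:
        k, a, v = self.kind, self.arg, self.value
        if k == "pos":
            if isinstance(v, frozenset):
                return f"pos({a}) in {_fmt_set(v)}"
            return f"pos({a})={'del' if v == '-' else v}"
        if k in ("loop1len", "loop2len", "loop3len", "ctail", "nterm_ext"):
            if isinstance(v, tuple):
                return f"{k} in {v[0]}..{v[1]}"
            return f"{k}={v}"
        if k in ("ncys", "anchors"):
            return f"{k}={v}"
        if k == "xcys":
            return f"extra_cys_at({a})"
        if k == "fifth":
            return f"fifth_ss_loop={v}"
        if k == "proflanks":
            return f"proflanks={_fmt_set(v)}"
        if k == "motif":
            return f"{'motif' if v else 'nomotif'}({a},loop2)"
        if k in ("cterm_gly", "nterm_gln", "covalent"):
            return f"{k}={1 if v else 0}"
        if k == "procsite":
            return f"procsite({v})"
        if k == "procmotif":
            if isinstance(v, frozenset):
                return f"procmotif in {_fmt_set(v)}"
            return f"procmotif({v})"
        if k == "dimer":
            return f"dimer_model({a},{v})"
        raise DSLError(f"unrenderable clause kind {k}")

    # ---- evaluation ------------------------------------------------------
    def evaluate(self, fv) -> bool | None:
        k, a, v = self.kind, self.arg, self.value
        if k == "pos":
            res = fv.site(a)
            if res is None or res == "X":
                return None
            if isinstance(v, frozenset):
                return res in v
            return res == v
        if k in ("loop1len", "loop2len", "loop3len", "ctail"):
            n = {"loop1len": fv.loop1len, "loop2len": fv.loop2len,
                 "loop3len": fv.loop3len, "ctail": fv.ctail_len}[k]
            if n is None:
                return None
            return v[0] <= n <= v[1] if isinstance(v, tuple) else n == v
        if k == "nterm_ext":
            n = fv.nterm_ext
            if n is None:
                return None
            return v[0] <= n <= v[1] if isinstance(v, tuple) else n == v
        if k == "ncys":
            return fv.ncys == v
        if k == "anchors":
            return fv.anchors_matched == v
        if k == "xcys":
            return a in fv.extra_cys_cols
        if k == "fifth":
            return fv.fifth_ss_loop == v
        if k == "proflanks":
            return frozenset(fv.pro_flanks) == v
        if k == "motif":
            hit = any(m[0] == a and m[1] == "loop2" for m in fv.motifs)
            return hit if v else not hit
        if k == "cterm_gly":
            return fv.cterm_gly == v
        if k == "nterm_gln":
            return fv.nterm_gln == v
        if k == "covalent":
            return fv.covalent == v
        if k == "procsite":
            if fv.procsite is None:
                return None
            return fv.procsite == v
        if k == "procmotif":
            if fv.procsite is None:
                return None
            m = fv.procmotif or ""
            return m in v if isinstance(v, frozenset) else m == v
        if k == "dimer":
            frac = fv.dimer_scores.get(a)
            if frac is None:
                return None
            return frac >= v
        raise DSLError(f"unevaluable clause kind {k}")


@dataclass(frozen=True)
class Predicate:
    clauses: tuple[Clause, ...]

    @property
    def specificity(self) -> int:
        return len(self.clauses)

    def render(self) -> str:
        return " & ".join(c.render() for c in self.clauses)

    def evaluate(self, fv):
        """Return (n_satisfied, violated clause texts, unknown clause texts)."""
        sat, bad, unk = 0, [], []
        for c in self.clauses:
            r = c.evaluate(fv)
            if r is True:
                sat += 1
            elif r is False:
                bad.append(c.render())
            else:
                unk.append(c.render())
        return sat, bad, unk


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_INT = r"-?\d+"
_PATTERNS = [
    (re.compile(rf"^pos\(({_INT})\) in \{{([A-Z,]+)\}}$"),
     lambda m: Clause("pos", int(m[1]), frozenset(m[2].split(",")))),
    (re.compile(rf"^pos\(({_INT})\)=del$"),
     lambda m: Clause("pos", int(m[1]), "-")),
    (re.compile(rf"^pos\(({_INT})\)=([A-Z])$"),
     lambda m: Clause("pos", int(m[1]), m[2])),
    (re.compile(rf"^(loop[123]len|ctail|nterm_ext) in ({_INT})\.\.({_INT})$"),
     lambda m: Clause(m[1], None, (int(m[2]), int(m[3])))),
    (re.compile(rf"^(loop[123]len|ctail|nterm_ext|ncys|anchors)=({_INT})$"),
     lambda m: Clause(m[1], None, int(m[2]))),
    (re.compile(rf"^extra_cys_at\(({_INT})\)$"),
     lambda m: Clause("xcys", int(m[1]), True)),
    (re.compile(r"^fifth_ss_loop=(none|1|2)$"),
     lambda m: Clause("fifth", None, m[1])),
    (re.compile(r"^proflanks=\{([0-9,]*)\}$"),
     lambda m: Clause("proflanks", None,
                      frozenset(int(x) for x in m[1].split(",") if x))),
    (re.compile(r"^(motif|nomotif)\(([A-Z]+),loop2\)$"),
     lambda m: Clause("motif", m[2], m[1] == "motif")),
    (re.compile(r"^(cterm_gly|nterm_gln|covalent)=(0|1)$"),
     lambda m: Clause(m[1], None, m[2] == "1")),
    (re.compile(r"^procsite\((\w+)\)$"),
     lambda m: Clause("procsite", None, m[1])),
    (re.compile(r"^procmotif in \{([A-Z,]+)\}$"),
     lambda m: Clause("procmotif", None, frozenset(m[1].split(",")))),
    (re.compile(r"^procmotif\(([A-Z]+)\)$"),
     lambda m: Clause("procmotif", None, m[1])),
    (re.compile(r"^dimer_model\((\w+),([0-9.]+)\)$"),
     lambda m: Clause("dimer", m[1], float(m[2]))),
]


def parse_clause(text: str) -> Clause:
    text = text.strip()
    for pat, make in _PATTERNS:
        m = pat.match(text)
        if m:
            return make(m)
    raise DSLError(f"cannot parse clause {text!r}")


def parse_predicate(text: str) -> Predicate:
    parts = [p for p in text.split(" & ") if p.strip()]
    if not parts:
        raise DSLError("empty predicate")
    clauses = []
    for i, p in enumerate(parts, 1):
        try:
            clauses.append(parse_clause(p))
        except DSLError as exc:
            raise DSLError(f"clause {i}: {exc}") from None
    return Predicate(tuple(clauses))
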