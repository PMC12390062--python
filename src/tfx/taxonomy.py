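"""Taxonomy registry and the rule-based classifier.

The registry holds 158 leaves (family/class/group/subgroup), each with a
machine-evaluable conjunctive predicate.  Classification gates on family
first (the best-scoring alignment profile fixes the family), then evaluates
every leaf of that family: a uniquely fully-satisfied leaf is an *exact*
call, several are *ambiguous* (surfaced, never resolved silently), none
falls back to the *nearest* leaf by violated-clause count.  Quaternary
state of dimeric classes is sequence-inferred and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import criteria
from .dsl import Predicate, parse_predicate
from .features import FeatureVector, extract_features
from .frame import MasterFrame, align_to_frame, build_master_frame
from .records import ANNOTATION_COLUMNS, ToxinRecord

FAMILY_TOTALS = dict(criteria.FAMILY_TOTALS)


class RegistryError(ValueError):
    """Registry file or content violates an invariant."""


@dataclass(frozen=True)
class SubgroupCriteria:
    family: str
    cls: str
    group: str
    subgroup: str
    predicate: Predicate
    provenance: str
    exemplar: str = ""

    @property
    def path(self) -> str:
        parts = [self.family, self.cls]
        if self.group:
            parts.append(self.group)
        if self.subgroup:
            parts.append(self.subgroup)
        return "/".join(parts)

    @property
    def specificity(self) -> int:
        return self.predicate.specificity


@dataclass
class TaxonomyRegistry:
    leaves: list[SubgroupCriteria]
    version: str = "1"

    def __post_init__(self):
        paths = [l.path for l in self.leaves]
        dupes = {p for p in paths if paths.count(p) > 1}
        if dupes:
            raise RegistryError(f"duplicate leaf path(s): {sorted(dupes)}")
        counts: dict[str, int] = {}
        for leaf in self.leaves:
            counts[leaf.family] = counts.get(leaf.family, 0) + 1
        for fam, want in FAMILY_TOTALS.items():
            got = counts.get(fam, 0)
            if got != want:
                raise RegistryError(
                    f"family {fam}: {got} leaves, expected {want}")

    def family(self, name: str) -> list[SubgroupCriteria]:
        return [l for l in self.leaves if l.family == name]

    def __len__(self):
        return len(self.leaves)


def _split_path(path: str) -> tuple[str, str, str, str]:
    parts = path.split("/")
    family, cls = parts[0], parts[1]
    group = parts[2] if len(parts) > 2 else ""
    subgroup = parts[3] if len(parts) > 3 else ""
    return family, cls, group, subgroup


def builtin_registry() -> TaxonomyRegistry:
    """Registry built directly from the criteria tables."""
    leaves = []
    for spec in criteria.LEAVES:
        leaves.append(SubgroupCriteria(spec.family, spec.cls, spec.group,
                                       spec.subgroup, spec.clauses(),
                                       spec.note, spec.exemplar or ""))
    return TaxonomyRegistry(leaves)


def load_registry(path: str | Path | None = None) -> TaxonomyRegistry:
    """Load the registry from a TSV file (default: the shipped file).

    Columns: path, predicate, specificity, provenance, exemplar.
    """
    if path is None:
        text = resources.files("tfx").joinpath("data/registry.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0].split("\t")[0] != "path":
        raise RegistryError("registry file: missing header")
    leaves = []
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise RegistryError(f"registry line {ln}: expected 5 columns")
        path_s, pred_s, spec_s, prov, exemplar = fields
        try:
            pred = parse_predicate(pred_s)
        except Exception as exc:
            raise RegistryError(f"registry line {ln} ({path_s}): {exc}") from None
        if int(spec_s) != pred.specificity:
            raise RegistryError(
                f"registry line {ln} ({path_s}): specificity mismatch")
        fam, cls, grp, sub = _split_path(path_s)
        leaves.append(SubgroupCriteria(fam, cls, grp, sub, pred, prov,
                                       exemplar))
    return TaxonomyRegistry(leaves)


@dataclass
class ClassificationResult:
    id: str
    best: str | None                       # leaf path or None
    confidence: str                        # exact | ambiguous | nearest | unclassified
    matches: list[tuple[str, int, list[str]]]   # (path, satisfied, violated)
    features: FeatureVector | None
    notes: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        fv = self.features
        fam = cls = grp = sub = "-"
        if self.best:
            fam, cls, grp, sub = _split_path(self.best)
        sat, vio = "-", "-"
        if self.matches:
            sat = self.matches[0][1]
            vio = len(self.matches[0][2])
        site = flanks = motifs = ""
        row = {
            "id": self.id, "family": fam, "class": cls, "group": grp or "-",
            "subgroup": sub or "-", "confidence": self.confidence,
            "satisfied": sat, "violated": vio,
        }
        if fv is None:
            row.update({c: "-" for c in ANNOTATION_COLUMNS if c not in row})
            return row
        site_cols = sorted({cl.arg for m in self.matches[:1]
                            for cl in _leaf_pos_cols(m[0])}) if self.best else []
        site = ";".join(f"{c}:{fv.site(c) or '?'}" for c in site_cols)
        flanks = ";".join(str(c) for c in sorted(fv.pro_flanks))
        motifs = ";".join(f"{m}@{reg}" for m, reg, _ in fv.motifs)
        ann = fv.propeptide
        row.update({
            "ncys": fv.ncys, "fifth_ss_loop": fv.fifth_ss_loop,
            "loop1len": _d(fv.loop1len), "loop2len": _d(fv.loop2len),
            "loop3len": _d(fv.loop3len), "ctail_len": _d(fv.ctail_len),
            "site_residues": site, "pro_flanks": flanks, "motifs": motifs,
            "cterm_gly": int(fv.cterm_gly), "nterm_gln": int(fv.nterm_gln),
            "nterm_ext_len": _d(fv.nterm_ext),
            "processing_site": fv.procsite or "-",
            "notes": ";".join(sorted(set(self.notes) | fv.flags)) or "-",
        })
        return row


def _d(v):
    return "-" if v is None else v


_POS_COL_CACHE: dict[str, tuple] = {}


def _leaf_pos_cols(path: str):
    if path not in _POS_COL_CACHE:
        try:
            spec = criteria.leaf_by_path(path)
            cols = tuple(c for c in spec.clauses().clauses if c.kind == "pos")
        except KeyError:
            cols = ()
        _POS_COL_CACHE[path] = cols
    return _POS_COL_CACHE[path]


def classify(fv: FeatureVector, registry: TaxonomyRegistry) -> ClassificationResult:
    """Assign a feature vector to a taxonomy leaf (or nearest / unclassified)."""
    notes = []
    if fv.anchors_matched < 6:
        return ClassificationResult(fv.record_id, None, "unclassified", [],
                                    fv, ["family gates failed"])
    leaves = registry.family(fv.family)
    if not leaves:
        return ClassificationResult(fv.record_id, None, "unclassified", [],
                                    fv, [f"no registry family {fv.family}"])
    scored = []
    for leaf in leaves:
        sat, violated, unknown = leaf.predicate.evaluate(fv)
        scored.append((leaf, sat, violated, unknown))
    scored.sort(key=lambda t: (-t[1], -t[0].specificity, t[0].path))
    full = [t for t in scored if not t[2] and not t[3]]
    matches = [(leaf.path, sat, violated) for leaf, sat, violated, _ in scored]
    if len(full) == 1:
        conf, best = "exact", full[0][0].path
    elif len(full) > 1:
        conf, best = "ambiguous", full[0][0].path
        notes.append("also fully satisfied: "
                     + ",".join(t[0].path for t in full[1:]))
    else:
        conf, best = "nearest", min(
            scored, key=lambda t: (len(t[2]) + len(t[3]),
                                   -t[0].specificity, t[0].path))[0].path
        unknown = next(t[3] for t in scored if t[0].path == best)
        if unknown:
            notes.append("unknown clauses: " + ";".join(unknown))
    return ClassificationResult(fv.record_id, best, conf, matches[:5], fv,
                                notes)


def registry_stats(registry: TaxonomyRegistry) -> dict[str, dict[str, int]]:
    """Per-family (classes, groups, subgroups) counts."""
    out: dict[str, dict[str, int]] = {}
    for fam in FAMILY_TOTALS:
        leaves = registry.family(fam)
        classes = {l.cls for l in leaves}
        groups = {(l.cls, l.group) for l in leaves}
        out[fam] = {"classes": len(classes), "groups": len(groups),
                    "subgroups": len(leaves)}
    out["total"] = {"classes": sum(v["classes"] for v in out.values()),
                    "groups": sum(v["groups"] for v in out.values()),
                    "subgroups": sum(v["subgroups"] for v in out.values())}
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def classify_records(records: list[ToxinRecord],
                     frame: MasterFrame | None = None,
                     registry: TaxonomyRegistry | None = None
                     ) -> list[ClassificationResult]:
    """Process → align → extract → classify a batch of records."""
    from .precursor import mature_record, nterm_extension

    frame = frame or build_master_frame()
    registry = registry or load_registry()
    results = []
    for rec in records:
        ann = None
        if rec.form == "precursor_signal_removed":
            rec, ann = mature_record(rec)
        elif rec.form == "precursor_with_signal":
            raise ValueError(f"{rec.id}: remove the signal peptide first "
                             "(form=precursor_signal_removed)")
        if rec.residues.count("C") < 2:
            results.append(ClassificationResult(
                rec.id, None, "unclassified", [], None,
                ["too few cysteines for a three-finger scaffold"]))
            continue
        aligned = align_to_frame(rec, frame)
        fv = extract_features(aligned, propeptide=ann)
        if ann is not None:
            ann.nterm_ext_len = nterm_extension(aligned)
        results.append(classify(fv, registry))
    return results
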