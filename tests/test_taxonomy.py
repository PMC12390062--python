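"""Registry loading, invariants and classification behaviour."""

import pytest

from tfx import (ToxinRecord, builtin_registry, classify_records,
                 load_registry, registry_stats)
from tfx.dsl import DSLError, parse_predicate
from tfx.synthdata import generate_leaf, mutate
from tfx.taxonomy import RegistryError

EXPECTED_TOTALS = {"TypeI": 36, "TypeII": 56, "TypeIII": 3,
                   "NonConventional": 20, "Omega": 5, "Sigma": 7,
                   "Colubrid": 31}


def test_registry_cardinalities(registry):
    stats = registry_stats(registry)
    for fam, want in EXPECTED_TOTALS.items():
        assert stats[fam]["subgroups"] == want
    assert stats["total"]["subgroups"] == 158
    assert stats["total"]["subgroups"] >= 150


def test_registry_structure_counts(registry):
    stats = registry_stats(registry)
    assert stats["TypeI"]["classes"] == 9
    assert stats["TypeII"]["classes"] == 6
    assert stats["Colubrid"]["classes"] == 11
    assert stats["Omega"]["groups"] == 5


def test_builtin_and_shipped_registry_agree(registry):
    built = builtin_registry()
    assert len(built) == len(registry)
    shipped = {l.path: l.predicate.render() for l in registry.leaves}
    for leaf in built.leaves:
        assert shipped[leaf.path] == leaf.predicate.render()


def test_duplicate_path_rejected(tmp_path, registry):
    lines = ["path\tpredicate\tspecificity\tprovenance\texemplar"]
    for leaf in registry.leaves:
        lines.append("\t".join([leaf.path, leaf.predicate.render(),
                                str(leaf.specificity), leaf.provenance,
                                leaf.exemplar]))
    lines.append(lines[1])  # duplicate first leaf
    path = tmp_path / "reg.tsv"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(RegistryError, match="duplicate"):
        load_registry(path)


def test_dsl_syntax_error_reports_clause(tmp_path):
    with pytest.raises(DSLError, match="clause 2"):
        parse_predicate("ncys=8 & wibble(3)")


@pytest.mark.parametrize("leaf,want", [
    ("TypeI/1/1a", "TypeI/1/1a"),                 # erabutoxin profile
    ("TypeII/2/2c/via", "TypeII/2/2c/via"),       # alpha-cobratoxin profile
    ("TypeII/2/2a/iv", "TypeII/2/2a/iv"),         # alpha-bungarotoxin profile
    ("Omega/1/1a", "Omega/1/1a"),
    ("Sigma/1/1a", "Sigma/1/1a"),
])
def test_reference_profiles_classify_exact(frame, registry, leaf, want):
    rec = generate_leaf(leaf, 9, 1)[0]
    res = classify_records([rec], frame=frame, registry=registry)[0]
    assert (res.best, res.confidence) == (want, "exact")


def test_cys_free_peptide_unclassified(frame, registry):
    rec = ToxinRecord(id="r", residues="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
    res = classify_records([rec], frame=frame, registry=registry)[0]
    assert res.confidence == "unclassified"
    assert res.best is None


def test_single_site_mutant_goes_nearest_to_parent(frame, registry):
    # an edit at an undocumented decision value: no leaf matches fully
    rec = mutate(generate_leaf("TypeI/1/1a", 5, 1)[0], columns={37: "W"})
    res = classify_records([rec], frame=frame, registry=registry)[0]
    assert res.confidence == "nearest"
    assert res.best == "TypeI/1/1a"
    assert res.matches[0][2] == ["pos(37)=R"]


def test_matches_ranked_by_satisfied_then_specificity(frame, registry, cohort):
    _, truth, results = cohort
    for res in results[::13]:
        sats = [m[1] for m in res.matches]
        assert sats == sorted(sats, reverse=True)


def test_covalent_dimer_chains_classified_per_chain(frame, registry):
    rec = generate_leaf("TypeII/6/6a", 2, 1)[0]
    assert rec.metadata.get("covalent_dimer") == "1"
    res = classify_records([rec], frame=frame, registry=registry)[0]
    assert (res.best, res.confidence) == ("TypeII/6/6a", "exact")
    # the same chain without the covalent annotation is the monomeric leaf
    naked = ToxinRecord(id="m", residues=rec.residues)
    res = classify_records([naked], frame=frame, registry=registry)[0]
    assert (res.best, res.confidence) == ("TypeII/2/2c/via", "exact")


def test_registry_stats_match_printed_family_totals(registry):
    stats = registry_stats(registry)
    assert [stats[f]["subgroups"] for f in
            ("TypeI", "TypeII", "TypeIII", "NonConventional", "Omega",
             "Sigma", "Colubrid")] == [36, 56, 3, 20, 5, 7, 31]
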