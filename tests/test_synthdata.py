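"""Fixture generator: determinism, constraint preservation, mutation."""

import pytest

from tfx import classify_records
from tfx.criteria import LEAVES
from tfx.synthdata import (GenerationError, constrained_overrides,
                           generate_cohort, generate_leaf, mutate)


def test_same_seed_identical_output():
    a = generate_leaf("TypeII/2/2a/iv", 7, 3)
    b = generate_leaf("TypeII/2/2a/iv", 7, 3)
    assert [r.residues for r in a] == [r.residues for r in b]
    c = generate_leaf("TypeII/2/2a/iv", 8, 3)
    assert [r.residues for r in a] != [r.residues for r in c]


def test_cohort_one_per_leaf_all_labels_distinct():
    records, truth = generate_cohort(seed=4)
    assert len(records) == 158
    assert len(set(truth.values())) == 158
    assert all(rec.metadata["synthetic"] == "1" for rec in records)


def test_unknown_leaf_rejected():
    with pytest.raises(KeyError):
        generate_leaf("TypeI/9/9z", 1, 1)


def test_mutate_rate_zero_is_identity():
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    assert mutate(rec, rate=0.0).residues == rec.residues


def test_mutate_explicit_column_flips_leaf():
    rec = mutate(generate_leaf("TypeI/1/1a", 1, 1)[0], columns={36: "H"})
    assert "edits" in rec.metadata
    res = classify_records([rec])[0]
    assert (res.best, res.confidence) == ("TypeI/1/1b/i", "exact")


def test_mutate_out_of_range_rejected():
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    with pytest.raises(ValueError):
        mutate(rec, positions={999: "A"})
    with pytest.raises(ValueError):
        mutate(rec, columns={32: "A"})   # gap column for this layout


def test_free_position_mutation_preserves_label(frame, registry):
    picks = [l.path for l in LEAVES[::23]]
    for path in picks:
        rec = mutate(generate_leaf(path, 3, 1)[0], rate=0.05, seed=11)
        res = classify_records([rec], frame=frame, registry=registry)[0]
        assert (res.best, res.confidence) == (path, "exact"), path


def test_constrained_positions_never_mutated_at_rate():
    leaf = next(l for l in LEAVES if l.path == "TypeI/1/1a")
    rec = generate_leaf(leaf, 2, 1)[0]
    mut = mutate(rec, rate=1.0, seed=3)
    over = constrained_overrides(leaf)
    for col, res in over.items():
        pos = leaf.layout.pos_of(col)
        assert mut.residues[pos - 1] == res, col
    # with rate 1 every free position changed
    assert mut.residues != rec.residues


def test_unsatisfiable_template_raises_generation_error():
    leaf = next(l for l in LEAVES if l.path == "TypeI/1/1a")
    import copy
    broken = copy.deepcopy(leaf)
    broken.atoms["pos"][32] = "R"        # column 32 is a gap in this layout
    with pytest.raises(GenerationError, match="pos"):
        constrained_overrides(broken)
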