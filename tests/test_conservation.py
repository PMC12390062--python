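"""Conservation profiling: exact tallies, oracle equality, invariances."""

import random

import pytest

from tfx import align_to_frame, column_conservation, core_report
from tfx.synthdata import generate_leaf, mutate


@pytest.fixture(scope="module")
def aligned_group(frame):
    records = generate_leaf("TypeI/1/1a", 21, 20)
    return [align_to_frame(r, frame) for r in records]


def test_single_sequence_fully_conserved(frame):
    a = align_to_frame(generate_leaf("TypeI/1/1a", 1, 1)[0], frame)
    prof = column_conservation([a], columns=[27, 29, 37, 53])
    for col in (27, 29, 37, 53):
        assert prof.columns[col].conservation_pct == pytest.approx(100.0)


def test_hand_counted_mutant_fraction(frame):
    records = generate_leaf("TypeI/1/1a", 2, 10)
    records[3] = mutate(records[3], columns={27: "E"})
    aligned = [align_to_frame(r, frame) for r in records]
    prof = column_conservation(aligned, columns=[27])
    cc = prof.columns[27]
    assert cc.conservation_pct == pytest.approx(90.0)
    assert cc.substitutions[0] == ("E", 1)
    assert sum(cc.counts.values()) + cc.gaps == prof.n_sequences


def test_profile_equals_naive_frequency_count(aligned_group):
    cols = list(range(1, 69))
    prof = column_conservation(aligned_group, columns=cols)
    for col in cols:
        naive = {}
        gaps = 0
        for a in aligned_group:
            r = a.res_at.get(col)
            if r is None:
                gaps += 1
            else:
                naive[r] = naive.get(r, 0) + 1
        assert prof.columns[col].counts == naive
        assert prof.columns[col].gaps == gaps


def test_permutation_invariance(aligned_group):
    cols = [7, 27, 29, 37, 53]
    prof1 = column_conservation(aligned_group, columns=cols)
    shuffled = list(aligned_group)
    random.Random(5).shuffle(shuffled)
    prof2 = column_conservation(shuffled, columns=cols)
    for col in cols:
        assert prof1.columns[col].counts == prof2.columns[col].counts


def test_gaps_not_counted_as_substitutions(frame):
    short = align_to_frame(generate_leaf("TypeIII/1/1b", 1, 1)[0], frame)
    full = align_to_frame(generate_leaf("TypeIII/1/1a", 1, 1)[0], frame)
    prof = column_conservation([short, full], columns=[37],
                               canonical={37: "G"})
    cc = prof.columns[37]
    assert cc.gaps == 1 and cc.occupancy == 1
    assert cc.conservation_pct == pytest.approx(100.0)   # G over non-gap


def test_column_outside_frame_rejected(aligned_group):
    with pytest.raises(ValueError):
        column_conservation(aligned_group, columns=[500])


def test_core_report_lists_core_columns_and_matches_profile(aligned_group):
    prof = column_conservation(aligned_group,
                               columns=[7, 8, 10, 27, 29, 31, 36, 37, 42, 53])
    text = core_report(prof)
    core_idx = text.index("[core sites]")
    variant_idx = text.index("[variant sites]")
    core_block = text[core_idx:variant_idx]
    for col in (27, 29, 37, 53):
        assert f"col {col}" in core_block
    for col in (27, 29, 37, 53):
        pct = prof.columns[col].conservation_pct
        assert f"{pct:.1f}%" in core_block


def test_conservative_substitution_reported(frame):
    records = generate_leaf("TypeI/1/1a", 8, 10)
    records[0] = mutate(records[0], columns={37: "K"})   # Arg -> Lys, same class
    aligned = [align_to_frame(r, frame) for r in records]
    cc = column_conservation(aligned, columns=[37]).columns[37]
    assert cc.conservation_pct == pytest.approx(90.0)
    assert cc.conservative_pct == pytest.approx(100.0)
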