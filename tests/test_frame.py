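"""Homology frame: calibration, anchors, loop partition, aligner properties."""

import csv
from importlib import resources

import pytest

from tfx import ToxinRecord, align_to_frame, build_master_frame, partition_loops
from tfx.frame import FrameBuildError, _dp_align, _score
from tfx.layouts import CYS_ANCHOR_COLS, MIN_COL
from tfx.synthdata import generate_leaf
from tfx.templates import anchor_sequences


def _calibration_rows():
    text = resources.files("tfx").joinpath("data/calibration.tsv").read_text()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def _sequence_for(name, frame):
    """Ungapped sequence of an anchor-file entry."""
    return frame.anchor_toxins[name].replace("-", "")


def test_every_hard_calibration_pair_reproduced(frame):
    rows = [r for r in _calibration_rows() if r["status"] == "hard"]
    assert len(rows) >= 35
    by_toxin = {}
    for r in rows:
        by_toxin.setdefault(r["toxin_id"], []).append(r)
    bad = []
    for toxin, pairs in by_toxin.items():
        rec = ToxinRecord(id=toxin, residues=_sequence_for(toxin, frame))
        aligned = align_to_frame(rec, frame)
        for r in pairs:
            got = aligned.col_of.get(int(r["original_pos"]))
            if got != int(r["expected_column"]):
                bad.append((toxin, r["original_pos"], r["expected_column"], got))
    assert not bad, bad


def test_anchor_self_alignment_reproduces_seed_mapping(frame):
    for name in anchor_sequences():
        rec = ToxinRecord(id=name, residues=_sequence_for(name, frame))
        aligned = align_to_frame(rec, frame)
        assert aligned.col_of == frame.seed_mapping(name), name
        assert not aligned.flags


def test_frame_invariants(frame):
    assert frame.cys_anchor_indices == CYS_ANCHOR_COLS
    assert list(CYS_ANCHOR_COLS) == sorted(CYS_ANCHOR_COLS)
    for name, gapped in frame.anchor_toxins.items():
        for col in CYS_ANCHOR_COLS:
            assert gapped[col - MIN_COL] == "C", (name, col)


def test_build_rejects_anchor_without_cys(tmp_path, frame):
    bad = dict(frame.anchor_toxins)
    name, seq = next(iter(bad.items()))
    seq = list(seq)
    seq[3 - MIN_COL] = "A"
    path = tmp_path / "anchors.afa"
    path.write_text(f">{name} kind=anchor\n{''.join(seq)}\n")
    with pytest.raises(FrameBuildError, match=name):
        build_master_frame(path)


def test_numbering_monotonic_over_cohort(frame, cohort):
    records, _, _ = cohort
    from tfx.precursor import mature_record
    for rec in records[::7]:
        if rec.form != "mature":
            rec, _ = mature_record(rec)
        a = align_to_frame(rec, frame)
        pairs = sorted(a.col_of.items())
        cols = [c for _, c in pairs]
        assert cols == sorted(set(cols)), rec.id


def test_loop_partition_examples(frame):
    # short-chain reference: two residues after the last Cys
    era = ToxinRecord(id="e", residues=_sequence_for("erabutoxin_a", frame))
    loops = partition_loops(align_to_frame(era, frame))
    assert loops.length("ctail") == 2
    assert loops.length("loop1") == 13 and loops.length("loop2") == 16
    # long-chain class 1: shortest tails (4-5 residues)
    t2 = generate_leaf("TypeII/1/1a/i", 3, 1)[0]
    loops = partition_loops(align_to_frame(t2, frame))
    assert loops.ctail is not None and 4 <= loops.length("ctail") <= 5
    # long-chain class 3: the longest tails (17-24 residues)
    t3 = generate_leaf("TypeII/3/3c/i", 3, 1)[0]
    loops = partition_loops(align_to_frame(t3, frame))
    assert 17 <= loops.length("ctail") <= 24


def test_missing_anchor_cys_yields_flagged_partial_partition(frame):
    from tfx.precursor import mature_record
    rec = generate_leaf("Colubrid/11/a", 2, 1)[0]
    rec, _ = mature_record(rec)
    a = align_to_frame(rec, frame)
    assert "anchor_incomplete" in a.flags
    assert a.anchors_matched == 6
    assert set(a.unmatched_anchors) == {61, 66}
    loops = partition_loops(a)
    assert loops.ctail is None and loops.loop2 is not None


def test_loop2_insertion_shifts_loop3_positions_not_columns(frame):
    """Two extra loop II residues become insertions; loop III residues keep
    their columns while their original positions shift by the indel size."""
    base = generate_leaf("TypeI/1/1a", 4, 1)[0]
    a0 = align_to_frame(base, frame)
    seq = base.residues
    ins_at = 30  # inside loop II (0-based), before the tip
    rec = ToxinRecord(id="ins", residues=seq[:ins_at] + "GA" + seq[ins_at:])
    a1 = align_to_frame(rec, frame)
    for pos in range(44, 54):  # loop III region of the 62-residue reference
        assert a1.col_of.get(pos + 2) == a0.col_of.get(pos), pos


def _oracle_affine(query, prof, cfg):
    """Independent affine-gap global aligner over a column profile (slow,
    dict-state formulation) used to cross-check the production aligner."""
    from functools import lru_cache
    import sys
    sys.setrecursionlimit(100000)
    NEG = float("-inf")
    go, ge = cfg["gap_open_core"], cfg["gap_extend"]

    def gap_open(j):
        from tfx.frame import _gap_open
        return _gap_open(cfg, prof[j][0])

    n, m = len(query), len(prof)

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # best score aligning query[:i] against profile[:j], ending in state
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0:
                return NEG if j else 0.0
            if j == 0:
                return NEG
            s = _score(query[i - 1], prof[j - 1][1])
            if prof[j - 1][0] in CYS_ANCHOR_COLS and query[i - 1] == "C":
                s += cfg["anchor_bonus"]
            prev = max(best(i - 1, j - 1, st) for st in "MXY")
            return prev + s if prev > NEG else NEG
        if state == "X":  # profile column skipped
            if j == 0:
                return NEG
            if i == 0:
                return 0.0  # free leading columns
            cands = [best(i, j - 1, "M") + gap_open(j - 1) + ge,
                     best(i, j - 1, "X") + ge,
                     best(i, j - 1, "Y") + gap_open(j - 1) + ge]
            return max(cands)
        if i == 0:
            return NEG
        return max(best(i - 1, j, "M") + go + ge,
                   best(i - 1, j, "Y") + ge,
                   best(i - 1, j, "X") + go + ge)

    return max(best(n, j, st) for j in range(m + 1) for st in ("M", "Y"))


@pytest.mark.parametrize("indels", [0, 1, 2])
def test_aligner_matches_independent_oracle(frame, indels):
    base = generate_leaf("TypeI/1/1a", 6, 1)[0]
    seq = base.residues
    if indels:
        seq = seq[:28] + "G" * indels + seq[28:]
    rec = ToxinRecord(id="q", residues=seq)
    aligned = align_to_frame(rec, frame)
    prof = next(p for name, fam, p in frame.profiles if name == aligned.profile)
    score, _ = _dp_align(rec.residues, prof, frame.config)
    oracle = _oracle_affine(rec.residues, prof, frame.config)
    assert score == pytest.approx(oracle)
    assert aligned.score == pytest.approx(score)


def test_homology_label_notation(frame):
    era = ToxinRecord(id="e", residues=_sequence_for("erabutoxin_a", frame))
    a = align_to_frame(era, frame)
    assert a.homology_label(27) == "27"      # number unchanged: no bracket
    assert a.homology_label(33) == "33(37)"  # shifted by alignment gaps
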