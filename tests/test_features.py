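"""Feature extraction: Cys topology, sites, motifs, flanks, dimer scores."""

import pytest

from tfx import ToxinRecord, align_to_frame, extract_features, partition_loops
from tfx.features import (cys_profile, dimer_interface_score,
                          flanking_prolines, motif_scan, terminal_flags)
from tfx.precursor import mature_record
from tfx.synthdata import generate_leaf, mutate


def _fv(path, frame, seed=1):
    rec = generate_leaf(path, seed, 1)[0]
    ann = None
    if rec.form != "mature":
        rec, ann = mature_record(rec)
    aligned = align_to_frame(rec, frame)
    return extract_features(aligned, propeptide=ann), aligned


def test_erabutoxin_like_site_residues(frame):
    fv, _ = _fv("TypeI/1/1a", frame)
    want = {7: "Q", 8: "S", 10: "Q", 27: "K", 29: "W", 31: "D", 36: "F",
            37: "R", 42: "E", 53: "K"}
    assert {c: fv.site(c) for c in want} == want


def test_alpha_cobratoxin_like_site_residues(frame):
    fv, _ = _fv("TypeII/2/2c/via", frame)
    want = {27: "K", 29: "W", 31: "D", 33: "F", 37: "R", 40: "R", 53: "K",
            70: "F"}
    assert {c: fv.site(c) for c in want} == want


def test_cys_profiles_by_class(frame):
    fv, _ = _fv("TypeI/1/1a", frame)
    assert (fv.ncys, fv.extra_cys_cols) == (8, ())
    # ten-Cys class: surplus at the free-thiol columns 4 and 16
    fv, aligned = _fv("TypeI/3/3a", frame)
    assert fv.ncys == 10 and set(fv.extra_cys_cols) == {4, 16}
    prof = cys_profile(aligned)
    assert set(prof.free_thiol_candidates) == {4, 16}
    assert prof.n_cys == prof.anchor_matched + len(prof.extra_cys_cols)
    # non-conventional: the loop I pair is an intra-loop disulfide candidate
    fv, aligned = _fv("NonConventional/1/1a", frame)
    assert fv.fifth_ss_loop == "1"
    assert cys_profile(aligned).free_thiol_candidates == ()
    # long-chain: loop II tip pair
    fv, _ = _fv("TypeII/1/1a/i", frame)
    assert fv.fifth_ss_loop == "2"


def test_flanking_prolines(frame):
    _, aligned = _fv("TypeI/1/1a", frame)
    assert flanking_prolines(aligned) == {11, 50, 54}
    _, aligned = _fv("TypeI/1/1c/i", frame)
    flanks = flanking_prolines(aligned)
    assert 12 in flanks and 11 not in flanks
    rec = ToxinRecord(id="nopro", residues=generate_leaf(
        "TypeI/1/1i", 1, 1)[0].residues.replace("P", "A"))
    assert flanking_prolines(align_to_frame(rec, frame)) == set()


def test_motif_scan(frame):
    rec = generate_leaf("Colubrid/1/1a/i", 1, 1)[0]
    rec, _ = mature_record(rec)
    aligned = align_to_frame(rec, frame)
    hits = motif_scan(rec, partition_loops(aligned))
    loop2 = {(m, r) for m, r, _ in hits}
    assert ("CYTLY", "loop2") in loop2 and ("WAVK", "loop2") in loop2
    # integrin-binding tripeptide of the gamma-bungarotoxin class
    rec = generate_leaf("NonConventional/2", 1, 1)[0]
    hits = motif_scan(rec, partition_loops(align_to_frame(rec, frame)))
    assert any(m == "RGD" and r == "loop2" for m, r, _ in hits)
    # motif-free short-chain fixture
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    assert motif_scan(rec, None) == []


def test_terminal_flags():
    assert terminal_flags(ToxinRecord(id="a", residues="QCCKG")) == (True, True)
    assert terminal_flags(ToxinRecord(id="a", residues="MCCKA")) == (False, False)


def test_dimer_interface_scores(frame):
    _, aligned = _fv("TypeI/9", frame)
    assert dimer_interface_score(aligned, "haditoxin") == pytest.approx(1.0)
    # single-site ablation drops exactly one of k columns
    rec = mutate(generate_leaf("TypeI/9", 1, 1)[0], columns={23: "A"})
    ablated = align_to_frame(rec, frame)
    k = 5
    assert dimer_interface_score(ablated, "haditoxin") == pytest.approx((k - 1) / k)
    # Zn-site His -> Pro in the sigma group 1b scores the column absent
    _, aligned = _fv("Sigma/1/1b", frame)
    assert dimer_interface_score(aligned, "sigma") == pytest.approx(5 / 6)
    with pytest.raises(ValueError):
        dimer_interface_score(aligned, "nosuchmodel")


def test_dimer_score_monotone_under_ablation(frame):
    from tfx.features import DIMER_MODELS
    rec = generate_leaf("TypeII/4", 1, 1)[0]
    base = dimer_interface_score(align_to_frame(rec, frame), "kappa")
    score = base
    for col in sorted(DIMER_MODELS["kappa"]):
        rec = mutate(rec, columns={col: "D"})
        new = dimer_interface_score(align_to_frame(rec, frame), "kappa")
        assert new <= score + 1e-9
        score = new
    assert score < base


def test_extraction_is_pure(frame):
    rec = generate_leaf("Omega/1/1a", 1, 1)[0]
    a = align_to_frame(rec, frame)
    fv1, fv2 = extract_features(a), extract_features(a)
    assert fv1.res_at == fv2.res_at
    assert fv1.pro_flanks == fv2.pro_flanks
    assert fv1.motifs == fv2.motifs
    assert [fv1.loop1len, fv1.loop2len, fv1.loop3len, fv1.ctail_len] == \
        [fv2.loop1len, fv2.loop2len, fv2.loop3len, fv2.ctail_len]


def test_unknown_residue_makes_clause_unknown(frame):
    from tfx.dsl import parse_clause
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    seq = list(rec.residues)
    seq[32] = "X"   # original position 33 -> column 37
    xrec = ToxinRecord(id="x", residues="".join(seq))
    fv = extract_features(align_to_frame(xrec, frame))
    assert fv.site(37) is None
    assert parse_clause("pos(37)=R").evaluate(fv) is None
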