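"""Propeptide processing-site detection and N-terminal extensions."""

import pytest

from tfx import ToxinRecord, align_to_frame
from tfx.precursor import (detect_processing_site, mature_record,
                           nterm_extension)
from tfx.synthdata import generate_leaf

CASES = [
    # leaf, site type, pyroglu, nterm extension
    ("Colubrid/1/1a/i", "XaaGln", True, 7),
    ("Colubrid/1/1b", "tetrabasic", True, 7),
    ("Colubrid/1/1c", "dibasic", True, 7),
    ("Colubrid/1/1d", "dibasic", True, 17),
    ("Colubrid/1/1e", "monobasic", True, 6),
    ("Colubrid/2", "pentabasic_RRKKK", False, 5),
    ("Colubrid/3", "tribasic_KKK", False, 7),
    ("Colubrid/4", "dibasic", False, 6),
    ("Colubrid/5", "dibasic", False, 7),
    ("Colubrid/6", "monobasic", False, 6),
    ("Colubrid/7", "none", False, 3),
]


@pytest.mark.parametrize("leaf,site,pyroglu,ext", CASES)
def test_processing_site_and_extension(frame, leaf, site, pyroglu, ext):
    rec = generate_leaf(leaf, 1, 1)[0]
    ann = detect_processing_site(rec)
    assert ann.processing_site == site
    assert ann.pyroglu_candidate == pyroglu
    mature, _ = mature_record(rec, ann)
    assert len(rec.residues) == ann.propeptide_len + len(mature.residues)
    got_ext = nterm_extension(align_to_frame(mature, frame))
    assert got_ext == ext


def test_pentabasic_leaves_proline_start():
    rec = generate_leaf("Colubrid/2", 1, 1)[0]
    mature, ann = mature_record(rec)
    assert ann.site_motif == "RRKKK"
    assert mature.residues[0] == "P"


def test_xaa_gln_exposes_pyroglutamate_candidate():
    rec = generate_leaf("Colubrid/1/1a/i", 1, 1)[0]
    mature, ann = mature_record(rec)
    assert ann.processing_site == "XaaGln"
    assert mature.residues[0] == "Q"
    assert ann.pyroglu_candidate


def test_elapid_mature_has_zero_extension(frame):
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    assert nterm_extension(align_to_frame(rec, frame)) == 0


def test_mature_form_input_rejected():
    rec = generate_leaf("TypeI/1/1a", 1, 1)[0]
    with pytest.raises(ValueError, match="precursor"):
        detect_processing_site(rec)


def test_exactly_one_site_class_per_input():
    # a propeptide with both a monobasic and a dibasic run: the priority
    # order is total, the longer (higher-priority) run wins
    rec = ToxinRecord(
        id="p", residues="ASTKASTAKRQ" + "T" * 4
        + generate_leaf("TypeI/1/1a", 1, 1)[0].residues,
        form="precursor_signal_removed")
    ann = detect_processing_site(rec)
    assert ann.processing_site == "dibasic"
    assert ann.site_motif == "KR"


def test_no_site_means_absent_exon2():
    rec = generate_leaf("Colubrid/7", 1, 1)[0]
    ann = detect_processing_site(rec)
    assert ann.processing_site == "none"
    assert ann.exon2_class == "absent"
    assert ann.mature_start == 1
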