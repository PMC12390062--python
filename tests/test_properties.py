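"""Property-based invariants (hypothesis, derandomised)."""

import hypothesis.strategies as st
from hypothesis import given, settings

from tfx.criteria import LEAVES
from tfx.dsl import Clause, parse_predicate, Predicate
from tfx.records import ToxinRecord
from tfx.synthdata import generate_leaf, mutate

SETTINGS = dict(derandomize=True, max_examples=30, deadline=None)

_RES = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")
_COL = st.integers(min_value=-16, max_value=92)

_clause = st.one_of(
    st.builds(lambda c, r: Clause("pos", c, r), _COL, _RES),
    st.builds(lambda c: Clause("pos", c, "-"), _COL),
    st.builds(lambda c, rs: Clause("pos", c, frozenset(rs)), _COL,
              st.sets(_RES, min_size=2, max_size=4).map(tuple)),
    st.builds(lambda k, v: Clause(k, None, v),
              st.sampled_from(["loop1len", "loop2len", "loop3len", "ctail",
                               "ncys", "anchors", "nterm_ext"]),
              st.integers(min_value=0, max_value=30)),
    st.builds(lambda v: Clause("fifth", None, v),
              st.sampled_from(["none", "1", "2"])),
    st.builds(lambda cols: Clause("proflanks", None, frozenset(cols)),
              st.sets(st.sampled_from([7, 11, 12, 50, 54]), max_size=5)),
    st.builds(lambda m, pos: Clause("motif", m, pos),
              st.sampled_from(["CYTLY", "WAVK", "RGD"]), st.booleans()),
    st.builds(lambda k, v: Clause(k, None, v),
              st.sampled_from(["cterm_gly", "nterm_gln", "covalent"]),
              st.booleans()),
    st.builds(lambda m, f: Clause("dimer", m, f),
              st.sampled_from(["haditoxin", "kappa", "sigma", "dpp2d"]),
              st.floats(min_value=0.1, max_value=1.0).map(
                  lambda x: round(x, 2))),
)


@given(st.lists(_clause, min_size=1, max_size=8))
@settings(**SETTINGS)
def test_dsl_render_parse_round_trip(clauses):
    pred = Predicate(tuple(clauses))
    assert parse_predicate(pred.render()) == pred


@given(st.text(alphabet="acdefghiklmnpqrstvwyX", min_size=1, max_size=90))
@settings(**SETTINGS)
def test_record_normalisation_idempotent(seq):
    rec = ToxinRecord(id="r", residues=seq)
    again = ToxinRecord(id="r", residues=rec.residues)
    assert again.residues == rec.residues == seq.upper()


@given(st.sampled_from([l.path for l in LEAVES[::11]]),
       st.integers(min_value=0, max_value=2 ** 20))
@settings(**SETTINGS)
def test_generator_seed_determinism(path, seed):
    a = generate_leaf(path, seed, 1)[0]
    b = generate_leaf(path, seed, 1)[0]
    assert a.residues == b.residues and a.id == b.id


@given(st.sampled_from([l.path for l in LEAVES[::17]]))
@settings(**SETTINGS)
def test_mutation_edit_list_matches_sequence_difference(path):
    rec = generate_leaf(path, 3, 1)[0]
    mut = mutate(rec, rate=0.08, seed=5)
    diffs = sum(a != b for a, b in zip(rec.residues, mut.residues))
    edits = mut.metadata.get("edits", "")
    assert diffs == (len(edits.split(",")) if edits else 0)
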