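import pytest

import sarclink as sl
from sarclink.engine import Step1Outcome
from sarclink.signatures import Signature
from conftest import PROTO_SOURCE, PROTO_TARGET, make_source, make_target


def outcome(size, missing_source, cls="ambiguous", n_cand=2):
    present = frozenset(list("SsDLlCFRMO")[:size])
    missing = frozenset(list("OMRFC")[:missing_source])
    sig = Signature(present=present, missing_source=missing,
                    missing_target=frozenset(), conflicts=frozenset())
    return Step1Outcome("s0", cls, sig, [f"t{i}" for i in range(n_cand)])


@pytest.mark.parametrize(
    "size,missing,expected",
    [(5, 2, True), (4, 0, False), (8, 3, False), (6, 1, True), (10, 0, True)],
)
def test_step2_eligibility_rule(book, size, missing, expected):
    assert sl.eligible_for_step2(outcome(size, missing), book) is expected


def ambiguous_fixture(book, true_has_chemo=True, other_has_chemo=False):
    """One source tied between two targets distinguishable only by checking."""
    # source defines 8 slots (F, M missing -> step-2 eligible); both targets
    # agree on exactly S,s,L,l,C,O (death/resection undefined on their side)
    src_row = dict(
        PROTO_SOURCE,
        facility_code="", biopsy_date="",
        chemo_indication_date="2015-03-20",
    )
    base_tgt = dict(
        PROTO_TARGET,
        facility_code="", biopsy_date="", death_date="", resection_date="",
    )
    t0 = dict(base_tgt, patient_id="t0",
              chemo_date="2015-05-02" if true_has_chemo else "")
    t1 = dict(base_tgt, patient_id="t1", icd10_code="c41.9",
              chemo_date="2015-05-02" if other_has_chemo else "")
    return make_source(book, [src_row]), make_target(book, [t0, t1])


def test_checking_event_window_hit(book):
    source, target = ambiguous_fixture(book)
    hit = sl.evaluate_checking(source.records[0], target.by_id["t0"], book.checking)
    assert "c" in hit.hits
    miss = sl.evaluate_checking(source.records[0], target.by_id["t1"], book.checking)
    assert "c" not in miss.hits


def test_checking_event_outside_window_or_before_indication_misses(book):
    src = make_source(book, [dict(PROTO_SOURCE, chemo_indication_date="2014-05-02")]).records[0]
    tgt = make_target(book, [dict(PROTO_TARGET, chemo_date="2014-06-20")]).records[0]
    assert "c" in sl.evaluate_checking(src, tgt, book.checking).hits  # 49 d
    tgt_late = make_target(book, [dict(PROTO_TARGET, chemo_date="2015-06-20")]).records[0]
    assert "c" not in sl.evaluate_checking(src, tgt_late, book.checking).hits
    tgt_before = make_target(book, [dict(PROTO_TARGET, chemo_date="2014-04-20")]).records[0]
    assert "c" not in sl.evaluate_checking(src, tgt_before, book.checking).hits


def test_checking_code_mapping_hit(book):
    src = make_source(book, [dict(PROTO_SOURCE, tumor_type="soft tissue", tumor_site="limb")]).records[0]
    tgt = make_target(book, [dict(PROTO_TARGET, icd10_code="C49.1")]).records[0]
    assert "d" in sl.evaluate_checking(src, tgt, book.checking).hits
    tgt2 = make_target(book, [dict(PROTO_TARGET, icd10_code="C41.9")]).records[0]
    assert "d" not in sl.evaluate_checking(src, tgt2, book.checking).hits


def test_no_checking_fields_means_no_hits(book):
    src = make_source(book, [dict(PROTO_SOURCE, tumor_site="")]).records[0]
    tgt = make_target(book, [dict(PROTO_TARGET, chemo_date="", radio_date="",
                                  reexcision_date="", icd10_code="")]).records[0]
    assert sl.evaluate_checking(src, tgt, book.checking).n_hits == 0


def test_step2_resolves_single_hitter(book):
    source, target = ambiguous_fixture(book)
    outcomes = sl.step1_link(source, target, book=book)
    assert outcomes[0].outcome_class == "ambiguous"
    res = sl.step2_resolve(outcomes, source, target, book)
    assert len(res.resolved) == 1
    _, target_id, hit = res.resolved[0]
    assert target_id == "t0" and "c" in hit.hits
    assert res.still_ambiguous == []
    # audit log carries one hit vector per candidate
    assert set(res.log.target_id) == {"t0", "t1"}


def test_step2_unresolved_when_both_or_none_hit(book):
    for true_c, other_c in [(True, True), (False, False)]:
        source, target = ambiguous_fixture(book, true_c, other_c)
        outcomes = sl.step1_link(source, target, book=book)
        res = sl.step2_resolve(outcomes, source, target, book)
        assert res.resolved == []
        assert [o.source_id for o in res.still_ambiguous] == ["s0"]


def test_step2_skips_ineligible_outcomes(book):
    source, target = ambiguous_fixture(book)
    outcomes = sl.step1_link(source, target, book=book)
    strict = sl.LinkageBook(
        chaining=book.chaining, checking=book.checking,
        step2_min_signature=8, step2_max_missing=2,
    )
    res = sl.step2_resolve(outcomes, source, target, strict)
    assert res.resolved == [] and len(res.still_ambiguous) == 1


def test_step2_identity_when_checking_fields_missing(book):
    source, target = ambiguous_fixture(book, true_has_chemo=False)
    src = source.records[0]
    src.raw["chemo_indication_date"] = None
    outcomes = sl.step1_link(source, target, book=book)
    res = sl.step2_resolve(outcomes, source, target, book)
    assert res.resolved == []
    assert [o.source_id for o in res.still_ambiguous] == [o.source_id for o in outcomes]


def test_step2_rejects_non_ambiguous_input(book):
    with pytest.raises(ValueError):
        sl.step2_resolve([outcome(6, 0, cls="unique", n_cand=1)],
                         make_source(book, [PROTO_SOURCE]),
                         make_target(book, [PROTO_TARGET]), book)
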