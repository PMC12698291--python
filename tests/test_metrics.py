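import copy

import pytest

import sarclink as sl
from conftest import PROTO_SOURCE, PROTO_TARGET, make_source, make_target, random_instance
from linkage_oracle import brute_robustness
from sarclink.signatures import Signature


def run_pairs(source, target, book, **kw):
    index = sl.build_index(target, book)
    outcomes = sl.step1_link(source, target, index, book, **kw)
    pairs = []
    for o in outcomes:
        if o.outcome_class == "unique":
            p = sl.LinkedPair(o.source_id, o.candidate_ids[0], o.best_signature)
            p.robustness = sl.robustness(p, source, target, index, book, **kw)
            pairs.append(p)
    return pairs


def test_three_event_signature_unique_on_every_remainder_has_r2(book):
    # pair agreeing only on the three sampling/surgery dates, nothing else
    src = make_source(book, [dict(
        PROTO_SOURCE, sex="", birth_date="", town_code="", dept_code="",
        tumor_type="", facility_code="", death_date="",
    )]).records[0:1]
    source = sl.RecordSet(records=src, role="source")
    target = make_target(book, [dict(
        PROTO_TARGET, sex="", birth_date="", town_code="", dept_code="",
        tumor_type="", facility_code="", death_date="",
    )])
    pairs = run_pairs(source, target, book)
    assert len(pairs) == 1
    assert pairs[0].signature.present == frozenset("ORM")
    # any single remaining event date still identifies the pair uniquely
    assert pairs[0].robustness == 2


def test_decoy_sharing_all_but_one_variable_forces_r0(book):
    source = make_source(book, [PROTO_SOURCE])
    decoy = dict(PROTO_TARGET, patient_id="t1", resection_date="")
    target = make_target(book, [PROTO_TARGET, decoy])
    pairs = run_pairs(source, target, book)
    assert len(pairs) == 1 and pairs[0].target_id == "t0"
    # dropping R makes the decoy tie: R is indispensable
    assert pairs[0].robustness == 0


def test_robustness_undefined_for_step2_resolved_pairs(book):
    sig = Signature(frozenset("SsLlCO"), frozenset("FM"), frozenset("DR"), frozenset())
    p = sl.LinkedPair("s0", "t0", sig, step2_resolved=True)
    source = make_source(book, [PROTO_SOURCE])
    target = make_target(book, [PROTO_TARGET])
    index = sl.build_index(target, book)
    assert sl.robustness(p, source, target, index, book) is None
    assert sl.quality(p) == 0


def test_enumeration_matches_naive_reuniqueness_oracle():
    checked = 0
    for seed in range(8):
        source, target, book = random_instance(seed, n_source=8, n_target=50)
        for p in run_pairs(source, target, book):
            naive = brute_robustness(source.by_id[p.source_id], target, book, p.target_id)
            assert p.robustness == naive, (seed, p.source_id)
            checked += 1
    assert checked >= 10


def test_robustness_monotone_in_agreeing_variables():
    """Defining one more agreeing variable never decreases R."""
    for seed in range(4):
        source, target, book = random_instance(seed, n_source=8, n_target=50)
        index = sl.build_index(target, book)
        for p in run_pairs(source, target, book):
            src = source.by_id[p.source_id]
            tgt = target.by_id[p.target_id]
            for code in book.alphabet:
                if src.values.get(code) is not None or tgt.values.get(code) is None:
                    continue
                richer = copy.copy(src)
                richer.values = dict(src.values)
                richer.values[code] = tgt.values[code]
                rich_source = sl.RecordSet(
                    records=[richer if r.record_id == src.record_id else r
                             for r in source.records],
                    role="source",
                )
                new_pairs = [q for q in run_pairs(rich_source, target, book)
                             if q.source_id == p.source_id and q.target_id == p.target_id]
                if new_pairs:  # pair may stop being unique only if a tie appears; never here
                    assert new_pairs[0].robustness >= p.robustness


QUALITY_CASES = [
    (None, 6, 0, 0),
    (0, 4, 0, 1), (0, 4, 3, 1),  # bonus never applies below base 2
    (0, 5, 0, 2), (0, 5, 2, 3), (0, 9, 3, 4),
    (1, 5, 0, 3), (1, 5, 2, 4), (1, 5, 3, 5),
    (1, 6, 0, 4), (1, 8, 2, 5), (1, 8, 4, 6),
    (2, 3, 0, 5), (3, 9, 2, 6), (2, 4, 3, 7), (3, 10, 4, 7),
]


@pytest.mark.parametrize("r,size,hits,expected", QUALITY_CASES)
def test_quality_rule_examples(r, size, hits, expected):
    assert sl.quality_score(r, size, hits) == expected


def test_robustness_distribution_conserves_counts(book):
    sigs = [Signature(frozenset("SsLlO"), frozenset(), frozenset(), frozenset()),
            Signature(frozenset("SsDLlCFRMO"), frozenset(), frozenset(), frozenset())]
    pairs = [sl.LinkedPair(f"s{i}", f"t{i}", sigs[i % 2], robustness=i % 3)
             for i in range(9)]
    pairs.append(sl.LinkedPair("s9", "t9", sigs[0], step2_resolved=True))
    table = sl.robustness_distribution(pairs, book)
    assert table.n.sum() == 10
    single = sl.robustness_distribution([sl.LinkedPair("a", "b", sigs[0], robustness=1)], book)
    assert single.iloc[0].r_min == single.iloc[0].r_median == single.iloc[0].r_max == 1


def test_pairs_matched_on_two_dates_are_more_robust_than_one(book):
    """With demographics shared, a second agreeing event date adds robustness."""
    base_src = dict(PROTO_SOURCE, facility_code="", death_date="")
    base_tgt = dict(PROTO_TARGET, facility_code="", death_date="")
    # one event date (O); a decoy shares demographics, so O is indispensable
    src1 = dict(base_src, patient_id="p1", resection_date="", biopsy_date="")
    tgt1 = dict(base_tgt, patient_id="q1", resection_date="", biopsy_date="")
    decoy = dict(base_tgt, patient_id="q9", stay_start_date="2014-01-01",
                 resection_date="", biopsy_date="")
    # two event dates (O and R)
    src2 = dict(base_src, patient_id="p2", biopsy_date="", town_code="10001", dept_code="10")
    tgt2 = dict(base_tgt, patient_id="q2", biopsy_date="", town_code="10001", dept_code="10")
    source = make_source(book, [src1, src2])
    target = make_target(book, [tgt1, tgt2, decoy])
    pairs = {p.source_id: p for p in run_pairs(source, target, book)}
    assert pairs["p1"].robustness < pairs["p2"].robustness
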