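import numpy as np

import sarclink as sl
from conftest import PROTO_SOURCE, PROTO_TARGET, make_source, make_target, random_instance
from linkage_oracle import brute_signature, brute_step1


def test_planted_pair_without_decoy_is_unique(book):
    source = make_source(book, [PROTO_SOURCE])
    target = make_target(
        book,
        [PROTO_TARGET, dict(PROTO_TARGET, patient_id="t1", sex="m",
                            birth_date="1951-01-01", stay_start_date="2011-06-01",
                            resection_date="2011-06-02", biopsy_date="2011-05-01",
                            death_date="")],
    )
    outcomes = sl.step1_link(source, target, book=book)
    assert outcomes[0].outcome_class == "unique"
    assert outcomes[0].candidate_ids == ["t0"]


def test_identical_twins_are_ambiguous(book):
    source = make_source(book, [PROTO_SOURCE])
    target = make_target(book, [PROTO_TARGET, dict(PROTO_TARGET, patient_id="t1")])
    out = sl.step1_link(source, target, book=book)[0]
    assert out.outcome_class == "ambiguous"
    assert out.candidate_ids == ["t0", "t1"]


def test_source_without_event_date_has_no_candidate(book):
    row = dict(PROTO_SOURCE, surgery_date="", resection_date="", biopsy_date="", death_date="")
    source = make_source(book, [row])
    target = make_target(book, [PROTO_TARGET])
    assert sl.step1_link(source, target, book=book)[0].outcome_class == "no_candidate"


def test_conflicting_candidate_disqualified_by_default_policy(book):
    # same dates but different sex: conflict on S,s -> no candidate retained
    source = make_source(book, [PROTO_SOURCE])
    target = make_target(book, [dict(PROTO_TARGET, sex="m")])
    assert sl.step1_link(source, target, book=book)[0].outcome_class == "no_candidate"
    # relaxing the conflict knob re-admits it
    out = sl.step1_link(source, target, book=book, max_conflicts=2)[0]
    assert out.outcome_class == "unique"


def test_step1_matches_exhaustive_scan_on_random_instances():
    for seed in range(10):
        source, target, book = random_instance(seed)
        outcomes = sl.step1_link(source, target, book=book)
        oracle = brute_step1(source, target, book)
        for o in outcomes:
            cls, winners = oracle[o.source_id]
            assert o.outcome_class == cls, o.source_id
            assert frozenset(o.candidate_ids) == winners


def test_step1_invariant_under_record_permutation():
    source, target, book = random_instance(3)
    base = {o.source_id: (o.outcome_class, tuple(o.candidate_ids))
            for o in sl.step1_link(source, target, book=book)}
    rev_source = sl.RecordSet(records=list(reversed(source.records)), role="source")
    rev_target = sl.RecordSet(records=list(reversed(target.records)), role="target")
    perm = {o.source_id: (o.outcome_class, tuple(o.candidate_ids))
            for o in sl.step1_link(rev_source, rev_target, book=book)}
    assert base == perm


def test_best_signature_reproducible_for_unique_outcomes():
    source, target, book = random_instance(5)
    for o in sl.step1_link(source, target, book=book):
        if o.outcome_class == "unique":
            sig = sl.agreement_signature(
                source.by_id[o.source_id], target.by_id[o.candidate_ids[0]], book
            )
            assert sig == o.best_signature


def test_candidate_pool_grows_under_missingness():
    """Erasing any single source value never shrinks the zero-conflict pool."""
    import copy

    for seed in range(4):
        source, target, book = random_instance(seed, n_source=6, n_target=60)
        for src in source.records:
            base_pool = {
                t.record_id
                for t in target.records
                if not brute_signature(src, t, book)[1]
            }
            for code in book.alphabet:
                if src.values.get(code) is None:
                    continue
                reduced = copy.copy(src)
                reduced.values = dict(src.values)
                reduced.values[code] = None
                # erasing a fine variable erases its coarsenings' shared fields too
                pool = {
                    t.record_id
                    for t in target.records
                    if not brute_signature(reduced, t, book)[1]
                }
                assert base_pool <= pool


def test_noiseless_generation_recall_is_one():
    cfg = sl.SimulationConfig(n_source=100, n_target=1000, seed=7).noiseless()
    source, target, truth = sl.generate(cfg)
    outcomes = sl.step1_link(source, target, book=sl.default_book())
    assert all(o.outcome_class == "unique" for o in outcomes)
    assert all(o.candidate_ids == [truth.mapping[o.source_id]] for o in outcomes)
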