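import numpy as np
import pandas as pd
import pytest

import sarclink as sl
from sarclink._util import percentage
from sarclink.signatures import Signature
from conftest import PROTO_SOURCE, PROTO_TARGET, make_source, make_target


def _sig(present="SsDLlCFRMO"):
    p = frozenset(present)
    rest = frozenset(c for c in "SsDLlCFRMO" if c not in p)
    return Signature(p, rest, frozenset(), frozenset())


def small_result_and_truth(book):
    """Five planted records, four retained pairs, one of them false."""
    rows_s = [dict(PROTO_SOURCE, patient_id=f"s{i}") for i in range(5)]
    rows_t = [dict(PROTO_TARGET, patient_id=f"t{i}") for i in range(5)]
    source = make_source(book, rows_s)
    target = make_target(book, rows_t)
    truth = sl.TruthMap(
        mapping={f"s{i}": f"t{i}" for i in range(5)},
        corruption_log=pd.DataFrame(columns=["side", "record_id", "variable", "action", "detail"]),
    )
    pairs = [sl.LinkedPair(f"s{i}", f"t{i}", _sig(), robustness=2) for i in range(3)]
    pairs.append(sl.LinkedPair("s3", "t4", _sig(), robustness=0))  # planted false match
    for p in pairs:
        p.quality = sl.quality(p)
    from sarclink.engine import Step1Outcome

    outcomes = [Step1Outcome(f"s{i}", "unique", _sig(), [f"t{i}"]) for i in range(4)]
    outcomes.append(Step1Outcome("s4", "no_candidate", None, []))
    result = sl.LinkageResult(
        book=book, outcomes=outcomes, pairs=pairs, eliminated_groups=[],
        still_ambiguous_ids=[], no_candidate_ids=["s4"], demoted_collision_ids=[],
        n_source=5, target_collisions=0,
        step2_log=pd.DataFrame(columns=["source_id", "target_id", "hits", "n_hits"]),
        source=source,
    )
    return result, truth, source


def test_precision_recall_on_hand_instance(book):
    result, truth, _ = small_result_and_truth(book)
    report = sl.evaluate(result, truth)
    assert report.precision == pytest.approx(0.75)  # 3 correct of 4 retained
    assert report.recall == pytest.approx(0.6)  # 3 of 5 planted
    assert report.n_pairs + report.n_no_candidate + report.n_ambiguous_final \
        + report.n_eliminated == report.n_source


def test_evaluate_rejects_mismatched_ids(book):
    result, truth, _ = small_result_and_truth(book)
    truth.mapping["zz"] = "t9"
    with pytest.raises(ValueError, match="different source ids"):
        sl.evaluate(result, truth)


def test_empty_retained_set_reports_na_precision(book):
    result, truth, _ = small_result_and_truth(book)
    result.pairs = []
    report = sl.evaluate(result, truth)
    assert report.precision is None and report.recall == 0.0
    assert report.to_dict()["precision"] is None  # NA, never 0


def test_signature_frequency_table_ordering_and_shares(book):
    pairs = [sl.LinkedPair(f"a{i}", f"b{i}", _sig("SsLlO"), robustness=1) for i in range(6)]
    pairs += [sl.LinkedPair(f"c{i}", f"d{i}", _sig("SsDLlCFRMO"), robustness=2) for i in range(4)]
    t = sl.signature_frequency_table(pairs, book)
    assert t.iloc[0].n == 6 and t.iloc[1].n == 4
    assert t.n.sum() == 10
    assert t.cumulative_share.tolist() == [0.6, 1.0]
    assert t.iloc[0].r_median == 1


def test_death_date_audit(book):
    with_d = [sl.LinkedPair(f"a{i}", f"b{i}", _sig("SsDLlO"), robustness=1) for i in range(3)]
    with_d.append(sl.LinkedPair("a9", "b9", _sig("SsDLlO"), robustness=0))
    without = [sl.LinkedPair("x", "y", _sig("SsLlO"), robustness=2)]
    audit = sl.death_date_audit(with_d + without)
    assert audit.n_with_death == 4 and audit.n_robust == 3
    assert audit.pct_robust == 75.0
    empty = sl.death_date_audit(without)
    assert empty.n_with_death == 0 and empty.pct_robust is None


def test_death_audit_zero_when_death_is_sole_discriminator(book):
    # twin targets differing only in death date: D carries the whole link
    src = dict(PROTO_SOURCE, resection_date="", biopsy_date="", facility_code="")
    t_true = dict(PROTO_TARGET, resection_date="", biopsy_date="", facility_code="")
    t_twin = dict(t_true, patient_id="t1", death_date="2011-01-05")
    source = make_source(book, [src])
    target = make_target(book, [t_true, t_twin])
    result = sl.run_linkage(source, target, book, skip_step3=True)
    audit = sl.death_date_audit(result.pairs)
    assert audit.n_with_death == 1 and audit.n_robust == 0


def test_compare_paired_unpaired_percent_arithmetic(book):
    result, truth, source = small_result_and_truth(book)
    table = sl.compare_paired_unpaired(source, result)
    row = table[(table.group == "overall") & (table.status == "paired")].iloc[0]
    assert row.n == 4 and row.pct == 80.0
    non = table[(table.group == "overall") & (table.status == "nonpaired")].iloc[0]
    assert non.n == 1 and non.pct == 20.0
    assert row.pct + non.pct == 100.0
    # age at surgery: 1962-07-14 -> 2015-03-10 is 52 completed years
    assert row.age_mean == 52.0
    # registry-scale row percents follow the same half-up convention
    assert percentage(8362, 8362 + 1402, 1) == 85.6
    assert percentage(1402, 8362 + 1402, 1) == 14.4


def test_higher_missingness_subset_pairs_least():
    cfg = sl.SimulationConfig(n_source=600, n_target=4000, seed=9)
    source, target, truth = sl.generate(cfg)
    result = sl.run_linkage(source, target)
    rates = result.matching_rate_by_group()
    assert rates["pathological_base"] < rates["clinical_base"]
    table = sl.compare_paired_unpaired(source, result)
    by_group = table[table.status == "paired"].groupby("group")["n"].sum()
    paired_total = {g: by_group.get(g, 0) for g in ("clinical_base", "pathological_base")}
    assert paired_total["clinical_base"] > 0


def test_precision_ordering_across_quality_strata():
    cfg = sl.SimulationConfig(n_source=800, n_target=6000, seed=13)
    source, target, truth = sl.generate(cfg)
    result = sl.run_linkage(source, target)
    report = sl.evaluate(result, truth)
    prec = lambda qs: (  # noqa: E731
        sum(report.by_quality[q]["n_correct"] for q in qs),
        sum(report.by_quality[q]["n"] for q in qs),
    )
    low_q = [q for q in report.by_quality if q <= 2]
    high_q = [q for q in report.by_quality if q >= 5]
    c_hi, n_hi = prec(high_q)
    c_lo, n_lo = prec(low_q)
    if n_hi and n_lo:
        assert c_hi / n_hi >= c_lo / n_lo
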