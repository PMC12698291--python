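"""Independent brute-force reference implementations used as test oracles.

Everything here recomputes linkage quantities the slow, obvious way —
exhaustive Cartesian scans and naive re-uniqueness testing — without
touching the package's index, bitmask or enumeration machinery.
"""

from __future__ import annotations

from itertools import combinations


def _date_ok(spec, sdate, tdate) -> bool:
    delta = (tdate - sdate).days
    if spec.tolerance_direction == "symmetric":
        return abs(delta) <= spec.tolerance_days
    if spec.tolerance_direction == "target_not_after_source":
        return -spec.tolerance_days <= delta <= 0
    return 0 <= delta <= spec.tolerance_days


def brute_signature(src, tgt, book):
    """(present, conflicts) by direct pairwise comparison."""
    present, conflicts = set(), set()
    for spec in book.chaining:
        sv = src.values.get(spec.code)
        tv = tgt.values.get(spec.code)
        if sv is None or tv is None:
            continue
        if spec.kind == "date":
            ok = _date_ok(spec, sv, tv)
        elif spec.kind == "categorical_at_date":
            ok = sv[0] == tv[0] and _date_ok(spec, sv[1], tv[1])
        else:
            ok = sv == tv
        (present if ok else conflicts).add(spec.code)
    return present, conflicts


def brute_candidates(src, targets, book, max_conflicts=0):
    """Zero-conflict (or <=max_conflicts), >=1-event-date candidates with sizes."""
    event = {v.code for v in book.chaining if v.is_event}
    out = []
    for tgt in targets:
        present, conflicts = brute_signature(src, tgt, book)
        if len(conflicts) <= max_conflicts and present & event:
            out.append((tgt.record_id, present))
    return out


def brute_step1(source, target, book, max_conflicts=0):
    """Full Cartesian scan: source_id -> (class, frozenset of maximal candidates)."""
    results = {}
    for src in source.records:
        cands = brute_candidates(src, target.records, book, max_conflicts)
        if not cands:
            results[src.record_id] = ("no_candidate", frozenset())
            continue
        best = max(len(p) for _, p in cands)
        winners = frozenset(tid for tid, p in cands if len(p) == best)
        cls = "unique" if len(winners) == 1 else "ambiguous"
        results[src.record_id] = (cls, winners)
    return results


def _erase(record, codes):
    """Copy of a record with the given chaining codes set to missing."""
    import copy

    r = copy.copy(record)
    r.values = dict(record.values)
    for c in codes:
        r.values[c] = None
    return r


def brute_robustness(src, target, book, pair_target_id, max_conflicts=0):
    """Naive definition: largest k such that EVERY k-subset removal keeps the
    pair uniquely linked (uniqueness re-tested by full rescan)."""
    present, _ = brute_signature(src, target.by_id[pair_target_id], book)
    present = sorted(present)

    def unique_after(removal) -> bool:
        reduced = _erase(src, removal)
        cands = brute_candidates(reduced, target.records, book, max_conflicts)
        if not cands:
            return False
        best = max(len(p) for _, p in cands)
        winners = [tid for tid, p in cands if len(p) == best]
        return winners == [pair_target_id]

    for k in range(1, len(present)):
        if not all(unique_after(c) for c in combinations(present, k)):
            return k - 1
    return len(present) - 1
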