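"""Step 2 — disambiguation with checking variables.

Checking variables (default alphabet ``d``, ``e``, ``c``, ``r``) compare
information too noisy for primary chaining — a planned treatment actually
appearing in the care pathway within a window, or the stay's diagnosis code
mapping to the registry's tumor type/site — but good enough to separate two
otherwise tied candidates.

Only ambiguous outcomes whose signature is strong enough are examined: the
chaining signature must contain at least ``step2_min_signature`` variables
and the source record may have at most ``step2_max_missing`` undefined
chaining variables.  An eligible ambiguity resolves iff exactly one candidate
scores at least one checking hit and every other candidate scores none.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .book import CMP_CODE_MAPPING, CMP_EVENT_WINDOW, CheckingVariableSpec, LinkageBook
from .engine import CLASS_AMBIGUOUS, Step1Outcome
from .records import MISSING, Record, RecordSet


@dataclass(frozen=True)
class CheckingHit:
    source_id: str
    target_id: str
    hits: frozenset[str]

    @property
    def n_hits(self) -> int:
        return len(self.hits)


@dataclass
class Step2Result:
    resolved: list[tuple[Step1Outcome, str, CheckingHit]]  # (outcome, target_id, hit)
    still_ambiguous: list[Step1Outcome]
    log: pd.DataFrame  # per-candidate hit vectors, for audit


def eligible_for_step2(outcome: Step1Outcome, book: LinkageBook) -> bool:
    """Ambiguity strong enough to be worth checking (size and missingness rule)."""
    sig = outcome.best_signature
    return (
        sig is not None
        and sig.size >= book.step2_min_signature
        and sig.n_missing_source <= book.step2_max_missing
    )


def evaluate_checking(
    src: Record, tgt: Record, specs: list[CheckingVariableSpec] | tuple
) -> CheckingHit:
    """Evaluate every checking comparator for one candidate pair."""
    hits = set()
    for spec in specs:
        if spec.comparator == CMP_EVENT_WINDOW:
            s = src.raw.get(spec.source_fields[0], MISSING)
            t = tgt.raw.get(spec.target_fields[0], MISSING)
            if s is not MISSING and t is not MISSING:
                if 0 <= (t - s).days <= spec.window_days:
                    hits.add(spec.code)
        elif spec.comparator == CMP_CODE_MAPPING:
            mapping = spec.load_mapping()  # configuration error if absent
            code = tgt.raw.get(spec.target_fields[0], MISSING)
            parts = [src.raw.get(f, MISSING) for f in spec.source_fields]
            if code is not MISSING and all(p is not MISSING for p in parts):
                if mapping.get(code) == "/".join(str(p) for p in parts):
                    hits.add(spec.code)
    return CheckingHit(src.record_id, tgt.record_id, frozenset(hits))


def step2_resolve(
    ambiguous: list[Step1Outcome],
    source: RecordSet,
    target: RecordSet,
    book: LinkageBook,
) -> Step2Result:
    """Resolve eligible ambiguities; everything else passes through unchanged.

    Resolution is invariant to candidate order and never touches unique or
    no-candidate outcomes (they must not be passed in).
    """
    for o in ambiguous:
        if o.outcome_class != CLASS_AMBIGUOUS:
            raise ValueError(f"{o.source_id}: step 2 only accepts ambiguous outcomes")
    resolved = []
    still = []
    log_rows = []
    specs = book.checking
    for outcome in ambiguous:
        if not eligible_for_step2(outcome, book):
            still.append(outcome)
            continue
        src = source.by_id[outcome.source_id]
        hits = [
            evaluate_checking(src, target.by_id[tid], specs)
            for tid in outcome.candidate_ids
        ]
        for h in hits:
            log_rows.append(
                {
                    "source_id": h.source_id,
                    "target_id": h.target_id,
                    "hits": "".join(sorted(h.hits)),
                    "n_hits": h.n_hits,
                }
            )
        with_hit = [h for h in hits if h.n_hits >= 1]
        if len(with_hit) == 1:
            resolved.append((outcome, with_hit[0].target_id, with_hit[0]))
        else:
            still.append(outcome)
    log = pd.DataFrame(log_rows, columns=["source_id", "target_id", "hits", "n_hits"])
    return Step2Result(resolved=resolved, still_ambiguous=still, log=log)
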