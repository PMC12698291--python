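"""Step 1 — chaining.

For each source record the engine retrieves target candidates through the
inverted index, keeps those with no disagreeing co-defined chaining variable
(the default conflict policy; a ``max_conflicts`` knob relaxes it) and at
least one agreeing event-date variable, ranks them by signature size
(cardinality of the agreeing set — no per-variable weighting), and classifies
the record:

* ``no_candidate`` — nothing qualifies;
* ``unique`` — exactly one candidate attains the maximal signature size;
* ``ambiguous`` — two or more tie at the maximum (ties are never broken
  arbitrarily; they are handed to the disambiguation step).

The result is deterministic and independent of the order of the input
records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .book import LinkageBook
from .index import CandidateIndex, build_index
from .records import RecordSet
from .signatures import Signature, agreement_signature

CLASS_NO_CANDIDATE = "no_candidate"
CLASS_UNIQUE = "unique"
CLASS_AMBIGUOUS = "ambiguous"


@dataclass
class Step1Outcome:
    source_id: str
    outcome_class: str
    best_signature: Optional[Signature]  # unique/ambiguous only
    candidate_ids: list[str]  # maximal-signature candidates, sorted


def _bitcount(arr: np.ndarray) -> np.ndarray:
    return np.bitwise_count(arr)


def step1_link(
    source: RecordSet,
    target: RecordSet,
    index: Optional[CandidateIndex] = None,
    book: Optional[LinkageBook] = None,
    *,
    max_conflicts: int = 0,
) -> list[Step1Outcome]:
    """Classify every source record against the target set (see module doc)."""
    if index is None:
        if book is None:
            raise ValueError("either an index or a book must be given")
        index = build_index(target, book)
    book = book or index.book
    event_mask = np.uint32(book.event_bitmask)
    outcomes: list[Step1Outcome] = []
    for rec in source.records:
        pool = index.candidates_for(rec)
        if len(pool) == 0:
            outcomes.append(Step1Outcome(rec.record_id, CLASS_NO_CANDIDATE, None, []))
            continue
        agree, conflict = index.agreement_masks(rec, pool)
        ok = (_bitcount(conflict) <= max_conflicts) & ((agree & event_mask) != 0)
        if not ok.any():
            outcomes.append(Step1Outcome(rec.record_id, CLASS_NO_CANDIDATE, None, []))
            continue
        sizes = _bitcount(agree)
        best = sizes[ok].max()
        winners = pool[ok & (sizes == best)]
        cand_ids = sorted(index.ids[p] for p in winners)
        sig = agreement_signature(rec, target.by_id[cand_ids[0]], book)
        cls = CLASS_UNIQUE if len(cand_ids) == 1 else CLASS_AMBIGUOUS
        outcomes.append(Step1Outcome(rec.record_id, cls, sig, cand_ids))
    return outcomes
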