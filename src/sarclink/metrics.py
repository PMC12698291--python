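"""Pair-level confidence metrics: robustness R and quality Q.

Robustness of a pair that was unique on chaining alone is the largest number
of variables that can be dropped from its signature — any subset of that
size — without losing the uniqueness of the link.  ``R = 0`` means some
single variable is indispensable; ``R = 2`` means any two variables can go.
It is computed by exhaustive subset enumeration over the (≤ alphabet-size)
signature, re-testing uniqueness with the same candidate semantics as the
chaining step: dropping a source variable removes both its agreements and
its conflicts, so the candidate pool can only grow.

Quality folds robustness, signature size, and checking-variable hits into a
single 0–7 integer comparable across signature classes:

==============================  ======
condition                        base Q
==============================  ======
R undefined (step-2 resolved)      0
R = 0, size <= 4                   1
R = 0, size > 4                    2
R = 1, size <= 5                   3
R = 1, size > 5                    4
R >= 2                             5
==============================  ======

For base Q >= 2 exactly one bonus applies: +2 with >= 3 checking hits, else
+1 with exactly 2.  The bonuses are exclusive (not cumulative) so the scale
tops out at 7.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .book import LinkageBook
from .checking import CheckingHit
from .index import CandidateIndex
from .records import RecordSet
from .signatures import Signature


class LinkedPair:
    """A retained (source, target) pair with its signature and metrics."""

    __slots__ = (
        "source_id",
        "target_id",
        "signature",
        "robustness",
        "step2_resolved",
        "checking_hits",
        "quality",
    )

    def __init__(
        self,
        source_id: str,
        target_id: str,
        signature: Signature,
        robustness: Optional[int] = None,
        step2_resolved: bool = False,
        checking_hits: Optional[CheckingHit] = None,
        quality: Optional[int] = None,
    ):
        self.source_id = source_id
        self.target_id = target_id
        self.signature = signature
        self.robustness = robustness
        self.step2_resolved = step2_resolved
        self.checking_hits = checking_hits
        self.quality = quality
        if robustness is not None and not 0 <= robustness < signature.size:
            raise ValueError("robustness must lie in [0, signature size)")

    @property
    def n_hits(self) -> int:
        return 0 if self.checking_hits is None else self.checking_hits.n_hits


def robustness(
    pair: LinkedPair,
    source: RecordSet,
    target: RecordSet,
    index: CandidateIndex,
    book: Optional[LinkageBook] = None,
    *,
    max_conflicts: int = 0,
) -> Optional[int]:
    """Exact robustness by subset enumeration; None for step-2-resolved pairs."""
    if pair.step2_resolved:
        return None
    book = book or index.book
    rec = source.by_id[pair.source_id]
    pool = index.candidates_for(rec)
    agree, conflict = index.agreement_masks(rec, pool)
    event_mask = np.uint32(book.event_bitmask)
    # only targets with >=1 event-date agreement can ever be candidates
    keep = (agree & event_mask) != 0
    pool, agree, conflict = pool[keep], agree[keep], conflict[keep]
    ids = index.ids
    self_idx = next(i for i, p in enumerate(pool) if ids[p] == pair.target_id)
    slots = book.slots
    present_bits = sorted(slots[c] for c in pair.signature.present)
    size = len(present_bits)

    def unique_under(removed_mask: np.uint32) -> bool:
        keepm = np.uint32(~removed_mask & 0xFFFFFFFF)
        pres = agree & keepm
        conf = conflict & keepm
        cand = (np.bitwise_count(conf) <= max_conflicts) & ((pres & event_mask) != 0)
        if not cand[self_idx]:
            return False
        sizes = np.bitwise_count(pres)
        best = sizes[cand].max()
        winners = np.flatnonzero(cand & (sizes == best))
        return len(winners) == 1 and winners[0] == self_idx

    for k in range(1, size):
        for combo in combinations(present_bits, k):
            rm = np.uint32(0)
            for b in combo:
                rm |= np.uint32(1 << b)
            if not unique_under(rm):
                return k - 1
    return size - 1


def quality_score(r: Optional[int], size: int, n_hits: int) -> int:
    """The deterministic Q(R, size, hits) rule set (see module doc)."""
    if r is None:
        return 0
    if r == 0:
        base = 1 if size <= 4 else 2
    elif r == 1:
        base = 3 if size <= 5 else 4
    else:
        base = 5
    if base >= 2:
        if n_hits >= 3:
            base += 2
        elif n_hits == 2:
            base += 1
    return base


def quality(pair: LinkedPair) -> int:
    return quality_score(pair.robustness, pair.signature.size, pair.n_hits)


def robustness_distribution(
    pairs: list[LinkedPair],
    book: LinkageBook,
    group_by_signature: bool = True,
) -> pd.DataFrame:
    """Per-signature counts and robustness order statistics.

    Counts include step-2-resolved pairs (their R is undefined); the order
    statistics are computed over defined R only.  Group counts sum to the
    input size.
    """
    from .signatures import render_signature

    if not group_by_signature:
        pairs_by = {"all": list(pairs)}
    else:
        pairs_by = {}
        for p in pairs:
            pairs_by.setdefault(render_signature(p.signature, book), []).append(p)
    rows = []
    for key in sorted(pairs_by, key=lambda k: (-len(pairs_by[k]), k)):
        members = pairs_by[key]
        rs = [p.robustness for p in members if p.robustness is not None]
        rows.append(
            {
                "signature": key,
                "n": len(members),
                "r_min": min(rs) if rs else np.nan,
                "r_median": float(np.median(rs)) if rs else np.nan,
                "r_max": max(rs) if rs else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["signature", "n", "r_min", "r_median", "r_max"])
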