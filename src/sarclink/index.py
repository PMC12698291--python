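"""Inverted candidate index over the target database.

The linkage conceptually explores the full Cartesian product of source and
target records; the index is the data-organization device that makes this
tractable.  For every chaining variable it keeps an inverted map from
normalized value (dates keyed by calendar day, expanded to the tolerance
window at lookup time) to target record positions, plus integer-encoded
per-variable columns used for vectorized signature computation.

Retrieval through the index is exactly equivalent to the exhaustive scan:
a target can carry a non-empty event-date agreement with a source record
only if one of its event-date postings falls inside that record's window,
so the union of event-variable postings covers every possible candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .book import (
    KIND_CATEGORICAL,
    KIND_CATEGORICAL_AT_DATE,
    KIND_DATE,
    LinkageBook,
)
from .records import MISSING, Record, RecordSet

_MISS = -1  # encoded missing
_UNSEEN = -2  # source value never observed in the target


@dataclass
class CandidateIndex:
    book: LinkageBook
    ids: list[str]
    postings: dict  # code -> {key: np.ndarray of positions}
    cat_arrays: dict  # code -> int32 array (categorical part), _MISS where undefined
    date_arrays: dict  # code -> int32 array of date ordinals, _MISS where undefined
    value_ids: dict  # code -> {normalized categorical value: int}

    @property
    def n(self) -> int:
        return len(self.ids)

    # -- encoding -----------------------------------------------------------

    def encode_source(self, rec: Record) -> dict[str, tuple[int, int]]:
        """Encode a source record's chaining values as (cat_id, date_ordinal).

        Unused parts are ``_MISS``; a categorical value absent from the target
        encodes as ``_UNSEEN`` (agrees with nothing, conflicts with anything
        defined).
        """
        enc = {}
        for spec in self.book.chaining:
            v = rec.values.get(spec.code, MISSING)
            if v is MISSING:
                enc[spec.code] = (_MISS, _MISS)
                continue
            if spec.kind == KIND_DATE:
                enc[spec.code] = (0, v.toordinal())
            elif spec.kind == KIND_CATEGORICAL_AT_DATE:
                cid = self.value_ids[spec.code].get(v[0], _UNSEEN)
                enc[spec.code] = (cid, v[1].toordinal())
            else:
                cid = self.value_ids[spec.code].get(v, _UNSEEN)
                enc[spec.code] = (cid, _MISS)
        return enc

    # -- retrieval ----------------------------------------------------------

    def lookup(self, code: str, value) -> list[str]:
        """Target record ids posted under one exact key of one variable."""
        spec = self.book.by_code[code]
        if spec.kind == KIND_DATE:
            key = value.toordinal()
        elif spec.kind == KIND_CATEGORICAL_AT_DATE:
            key = (value[0], value[1].toordinal())
        else:
            key = value
        pos = self.postings[code].get(key)
        return [] if pos is None else [self.ids[p] for p in pos]

    def candidates_for(self, rec: Record) -> np.ndarray:
        """Positions of every target sharing ≥1 event-date agreement with ``rec``.

        Expands each defined event variable's date to its tolerance window and
        unions the postings.
        """
        chunks = []
        for spec in self.book.chaining:
            if not spec.is_event:
                continue
            v = rec.values.get(spec.code, MISSING)
            if v is MISSING:
                continue
            if spec.kind == KIND_DATE:
                d = v.toordinal()
                keyf = lambda o: o  # noqa: E731
            else:
                d = v[1].toordinal()
                cat = v[0]
                keyf = lambda o: (cat, o)  # noqa: E731
            lo, hi = spec.window(d)
            posts = self.postings[spec.code]
            for o in range(lo, hi + 1):
                arr = posts.get(keyf(o))
                if arr is not None:
                    chunks.append(arr)
        if not chunks:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(chunks))

    # -- vectorized agreement ----------------------------------------------

    def agreement_masks(
        self, rec: Record, pool: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-pool-member (agreement, conflict) bitmasks against ``rec``.

        Bit *i* of the agreement mask is set iff chaining slot *i* is defined
        on both sides and agrees; bit *i* of the conflict mask iff defined on
        both sides and disagrees.  Matches :func:`signatures.agreement_signature`.
        """
        npool = len(pool)
        agree_bits = np.zeros(npool, dtype=np.uint32)
        conflict_bits = np.zeros(npool, dtype=np.uint32)
        enc = self.encode_source(rec)
        for i, spec in enumerate(self.book.chaining):
            cid, sord = enc[spec.code]
            if cid == _MISS and sord == _MISS:
                continue
            bit = np.uint32(1 << i)
            if spec.kind == KIND_DATE:
                tv = self.date_arrays[spec.code][pool]
                defined = tv != _MISS
                lo, hi = spec.window(sord)
                agree = defined & (tv >= lo) & (tv <= hi)
            elif spec.kind == KIND_CATEGORICAL_AT_DATE:
                tc = self.cat_arrays[spec.code][pool]
                td = self.date_arrays[spec.code][pool]
                defined = tc != _MISS
                lo, hi = spec.window(sord)
                agree = (tc == cid) & (td >= lo) & (td <= hi)
            else:
                tc = self.cat_arrays[spec.code][pool]
                defined = tc != _MISS
                agree = tc == cid
            agree_bits |= np.where(agree, bit, 0).astype(np.uint32)
            conflict_bits |= np.where(defined & ~agree, bit, 0).astype(np.uint32)
        return agree_bits, conflict_bits


def build_index(rs: RecordSet, book: LinkageBook) -> CandidateIndex:
    """Build the inverted index and encoded columns from the target set."""
    if rs.role != "target":
        raise ValueError("candidate index is built over the target record set")
    n = len(rs.records)
    postings: dict = {}
    cat_arrays: dict = {}
    date_arrays: dict = {}
    value_ids: dict = {}
    for spec in book.chaining:
        posts: dict = {}
        cats = np.full(n, _MISS, dtype=np.int64)
        dates = np.full(n, _MISS, dtype=np.int64)
        vmap: dict = {}
        for pos, rec in enumerate(rs.records):
            v = rec.values.get(spec.code, MISSING)
            if v is MISSING:
                continue
            if spec.kind == KIND_DATE:
                key = v.toordinal()
                dates[pos] = key
                cats[pos] = 0
            elif spec.kind == KIND_CATEGORICAL_AT_DATE:
                cid = vmap.setdefault(v[0], len(vmap))
                o = v[1].toordinal()
                key = (v[0], o)
                cats[pos] = cid
                dates[pos] = o
            else:
                cid = vmap.setdefault(v, len(vmap))
                key = v
                cats[pos] = cid
            posts.setdefault(key, []).append(pos)
        postings[spec.code] = {k: np.asarray(p, dtype=np.int64) for k, p in posts.items()}
        cat_arrays[spec.code] = cats
        date_arrays[spec.code] = dates
        value_ids[spec.code] = vmap
    return CandidateIndex(
        book=book,
        ids=list(rs.ids),
        postings=postings,
        cat_arrays=cat_arrays,
        date_arrays=date_arrays,
        value_ids=value_ids,
    )
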