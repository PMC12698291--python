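"""Agreement signatures.

The *signature* of a (source, target) pair is the set of chaining variables
that are defined on both sides and agree (dates within their tolerance
window).  It renders as a fixed-slot string over the book's alphabet — the
slot letter when the variable is in the signature, ``.`` otherwise, e.g.
``"Ss.LlC.R.."`` under the default ten-slot book.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

from ._util import percentage
from .book import (
    KIND_CATEGORICAL_AT_DATE,
    KIND_DATE,
    ChainingVariableSpec,
    LinkageBook,
)
from .records import MISSING, Record


@dataclass(frozen=True)
class Signature:
    """Partition of the alphabet for one pair: agreeing, missing, conflicting."""

    present: frozenset[str]
    missing_source: frozenset[str]
    missing_target: frozenset[str]
    conflicts: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.present)

    @property
    def n_missing_source(self) -> int:
        return len(self.missing_source)


def dates_agree(spec: ChainingVariableSpec, source_date: _dt.date, target_date: _dt.date) -> bool:
    lo, hi = spec.window(source_date.toordinal())
    return lo <= target_date.toordinal() <= hi


def values_agree(spec: ChainingVariableSpec, sv, tv) -> bool:
    """Comparison semantics for two defined values of one chaining variable."""
    if spec.kind == KIND_DATE:
        return dates_agree(spec, sv, tv)
    if spec.kind == KIND_CATEGORICAL_AT_DATE:
        return sv[0] == tv[0] and dates_agree(spec, sv[1], tv[1])
    return sv == tv


def agreement_signature(src: Record, tgt: Record, book: LinkageBook) -> Signature:
    """Compute the full Signature of a (source, target) pair. Deterministic."""
    present, miss_s, miss_t, conflicts = set(), set(), set(), set()
    for spec in book.chaining:
        sv = src.values.get(spec.code, MISSING)
        tv = tgt.values.get(spec.code, MISSING)
        if sv is MISSING:
            miss_s.add(spec.code)
        if tv is MISSING:
            miss_t.add(spec.code)
        if sv is MISSING or tv is MISSING:
            continue
        if values_agree(spec, sv, tv):
            present.add(spec.code)
        else:
            conflicts.add(spec.code)
    return Signature(
        present=frozenset(present),
        missing_source=frozenset(miss_s),
        missing_target=frozenset(miss_t),
        conflicts=frozenset(conflicts),
    )


def render_signature(sig, book: LinkageBook) -> str:
    """Fixed-slot string: slot letter iff the code is present, '.' otherwise."""
    present = sig.present if isinstance(sig, Signature) else frozenset(sig)
    return "".join(v.code if v.code in present else "." for v in book.chaining)


def parse_signature(text: str, book: LinkageBook) -> frozenset[str]:
    """Inverse of :func:`render_signature` (recovers the present set)."""
    if len(text) != len(book.chaining):
        raise ValueError(
            f"signature string has {len(text)} slots, book has {len(book.chaining)}"
        )
    present = set()
    for ch, spec in zip(text, book.chaining):
        if ch == ".":
            continue
        if ch != spec.code:
            raise ValueError(f"slot for {spec.code!r} holds {ch!r}")
        present.add(spec.code)
    return frozenset(present)


def matching_rate(n_pairs: int, n_source_total: int) -> float:
    """Retained unique pairs over total source records, as a percent (1 dp)."""
    if n_source_total <= 0:
        raise ValueError("total number of source records must be positive")
    if not 0 <= n_pairs <= n_source_total:
        raise ValueError("pair count must lie in [0, n_source_total]")
    return percentage(n_pairs, n_source_total, 1)
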