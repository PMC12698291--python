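"""Step 3 — wholesale elimination of questionable signature groups.

A safety net applied after the unsupervised steps: whole groups of pairs
sharing a signature judged too weak are removed together, accepting the loss
of real positives in exchange for precision.  The five shipped rules encode
the reviewed criteria (absence of demographic or residency slots combined
with small signatures and source-side missingness); rules are data and can
be replaced.

Elimination depends only on the Signature (present set and source-side
missing count) — never on individual pair attributes — so two pairs with
identical signatures always share fate, and filtering is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .signatures import Signature


@dataclass(frozen=True)
class EliminationRule:
    rule_id: str
    description: str = ""
    requires_absent_all: frozenset[str] = frozenset()
    requires_absent_any: frozenset[str] = frozenset()
    min_missing: Optional[int] = None  # trigger if |missing_source| >= this
    max_size_exclusive: Optional[int] = None  # trigger if signature size < this

    def __post_init__(self) -> None:
        if not (
            self.requires_absent_all
            or self.requires_absent_any
            or self.min_missing is not None
            or self.max_size_exclusive is not None
        ):
            raise ValueError(f"rule {self.rule_id}: no trigger condition")
        if (self.min_missing or 0) < 0 or (self.max_size_exclusive or 0) < 0:
            raise ValueError(f"rule {self.rule_id}: thresholds must be non-negative")

    def triggers(self, sig: Signature) -> bool:
        present = sig.present
        if self.requires_absent_all and not all(c not in present for c in self.requires_absent_all):
            return False
        if self.requires_absent_any and not any(c not in present for c in self.requires_absent_any):
            return False
        if self.min_missing is not None and sig.n_missing_source < self.min_missing:
            return False
        if self.max_size_exclusive is not None and sig.size >= self.max_size_exclusive:
            return False
        return True


def default_rules() -> list[EliminationRule]:
    """The five shipped safety criteria."""
    return [
        EliminationRule(
            "R1",
            "signature lacks both S and s (no demographic information at all)",
            requires_absent_all=frozenset({"S", "s"}),
        ),
        EliminationRule(
            "R2",
            "signature lacks both L and l (no residency information at all)",
            requires_absent_all=frozenset({"L", "l"}),
        ),
        EliminationRule(
            "R3",
            "one of S or s absent, >=2 missing chaining variables, size < 6",
            requires_absent_any=frozenset({"S", "s"}),
            min_missing=2,
            max_size_exclusive=6,
        ),
        EliminationRule(
            "R4",
            "L absent, >=2 missing chaining variables, size < 8",
            requires_absent_all=frozenset({"L"}),
            min_missing=2,
            max_size_exclusive=8,
        ),
        EliminationRule(
            "R5",
            "one of L or l absent, >=2 missing chaining variables, size < 6",
            requires_absent_any=frozenset({"L", "l"}),
            min_missing=2,
            max_size_exclusive=6,
        ),
    ]


@dataclass
class EliminatedGroup:
    signature_string: str
    rule_id: str
    pairs: list  # LinkedPair

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass
class Step3Result:
    retained: list
    eliminated_groups: list[EliminatedGroup]

    @property
    def n_eliminated(self) -> int:
        return sum(g.size for g in self.eliminated_groups)


def step3_filter(pairs: list, rules: Optional[list[EliminationRule]] = None, book=None) -> Step3Result:
    """Partition pairs into retained and eliminated signature groups.

    Groups are keyed by (present set, source-side missing count); the first
    rule (in declaration order) that triggers names the group's elimination.
    """
    from .signatures import render_signature  # local import avoids cycle at import time

    if rules is None:
        rules = default_rules()
    groups: dict = {}
    order: list = []
    for p in pairs:
        key = (p.signature.present, p.signature.n_missing_source)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)
    retained: list = []
    eliminated: list[EliminatedGroup] = []
    for key in order:
        members = groups[key]
        sig = members[0].signature
        hit = next((r for r in rules if r.triggers(sig)), None)
        if hit is None:
            retained.extend(members)
        else:
            sig_str = (
                render_signature(sig, book)
                if book is not None
                else "".join(sorted(sig.present))
            )
            eliminated.append(EliminatedGroup(sig_str, hit.rule_id, members))
    return Step3Result(retained=retained, eliminated_groups=eliminated)
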