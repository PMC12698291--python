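"""End-to-end linkage pipeline: chaining → disambiguation → elimination → metrics.

:func:`run_linkage` wires the three steps and the pair metrics into a single
:class:`LinkageResult` that partitions every source record into exactly one
of four buckets — retained pair, no candidate, still ambiguous, eliminated —
and exposes the matching rates and report tables computed on them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._util import percentage
from .book import LinkageBook, default_book
from .checking import CheckingHit, Step2Result, evaluate_checking, step2_resolve
from .elimination import EliminationRule, Step3Result, step3_filter
from .engine import (
    CLASS_AMBIGUOUS,
    CLASS_NO_CANDIDATE,
    CLASS_UNIQUE,
    Step1Outcome,
    step1_link,
)
from .index import CandidateIndex, build_index
from .metrics import LinkedPair, quality, robustness
from .records import (
    SUBSET_BOTH,
    SUBSET_CLINICAL,
    SUBSET_PATHOLOGICAL,
    RecordSet,
)
from .signatures import matching_rate, render_signature

# reporting groups over the three source subsets: the clinical base, the
# pathological base (both overlap on the intersection) and the whole set
GROUPS = {
    "overall": (SUBSET_BOTH, SUBSET_CLINICAL, SUBSET_PATHOLOGICAL),
    "clinical_base": (SUBSET_BOTH, SUBSET_CLINICAL),
    "pathological_base": (SUBSET_BOTH, SUBSET_PATHOLOGICAL),
    "intersection": (SUBSET_BOTH,),
}


@dataclass
class LinkageResult:
    book: LinkageBook
    outcomes: list[Step1Outcome]
    pairs: list[LinkedPair]  # retained (definitive) pairs
    eliminated_groups: list
    still_ambiguous_ids: list[str]
    no_candidate_ids: list[str]
    demoted_collision_ids: list[str]
    n_source: int
    target_collisions: int  # targets claimed by >=2 retained pairs
    step2_log: pd.DataFrame
    flags: dict = field(default_factory=dict)
    source: Optional[RecordSet] = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_no_candidate(self) -> int:
        return len(self.no_candidate_ids)

    @property
    def n_ambiguous_final(self) -> int:
        return len(self.still_ambiguous_ids) + len(self.demoted_collision_ids)

    @property
    def n_eliminated(self) -> int:
        return sum(len(g.pairs) for g in self.eliminated_groups)

    @property
    def definitive_matching_rate(self) -> float:
        return matching_rate(self.n_pairs, self.n_source)

    def matching_rate_by_group(self) -> dict[str, Optional[float]]:
        """Definitive matching rate per reporting group (None when empty)."""
        if self.source is None:
            return {"overall": self.definitive_matching_rate}
        paired = {p.source_id for p in self.pairs}
        rates: dict[str, Optional[float]] = {}
        for g, subsets in GROUPS.items():
            members = [r for r in self.source.records if (r.subset or SUBSET_BOTH) in subsets]
            if not members:
                rates[g] = None
                continue
            n = sum(1 for r in members if r.record_id in paired)
            rates[g] = matching_rate(n, len(members))
        return rates

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_id": p.source_id,
                "target_id": p.target_id,
                "signature": render_signature(p.signature, self.book),
                "size": p.signature.size,
                "n_missing_source": p.signature.n_missing_source,
                "robustness": "" if p.robustness is None else p.robustness,
                "hits": "" if p.checking_hits is None else "".join(sorted(p.checking_hits.hits)),
                "n_hits": p.n_hits,
                "quality": p.quality,
                "step2_resolved": int(p.step2_resolved),
            }
            for p in self.pairs
        ]
        cols = [
            "source_id",
            "target_id",
            "signature",
            "size",
            "n_missing_source",
            "robustness",
            "hits",
            "n_hits",
            "quality",
            "step2_resolved",
        ]
        return pd.DataFrame(rows, columns=cols)

    def outcomes_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_id": o.source_id,
                "class": o.outcome_class,
                "signature": ""
                if o.best_signature is None
                else render_signature(o.best_signature, self.book),
                "n_candidates": len(o.candidate_ids),
            }
            for o in self.outcomes
        ]
        return pd.DataFrame(rows, columns=["source_id", "class", "signature", "n_candidates"])

    def eliminated_frame(self) -> pd.DataFrame:
        rows = [
            {"signature": g.signature_string, "rule_id": g.rule_id, "group_size": g.size}
            for g in self.eliminated_groups
        ]
        return pd.DataFrame(rows, columns=["signature", "rule_id", "group_size"])

    def summary(self) -> dict:
        """Deterministic machine-readable scalar summary."""
        q_counts = {}
        for p in self.pairs:
            q_counts[p.quality] = q_counts.get(p.quality, 0) + 1
        return {
            "n_source": self.n_source,
            "n_pairs": self.n_pairs,
            "n_no_candidate": self.n_no_candidate,
            "n_ambiguous_final": self.n_ambiguous_final,
            "n_eliminated": self.n_eliminated,
            "n_step2_resolved": sum(1 for p in self.pairs if p.step2_resolved),
            "target_collisions": self.target_collisions,
            "definitive_matching_rate": self.definitive_matching_rate,
            "matching_rate_by_group": {
                k: v for k, v in sorted(self.matching_rate_by_group().items())
            },
            "quality_distribution": {str(k): q_counts[k] for k in sorted(q_counts)},
            "flags": {k: self.flags[k] for k in sorted(self.flags)},
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"


def run_linkage(
    source: RecordSet,
    target: RecordSet,
    book: Optional[LinkageBook] = None,
    *,
    skip_step2: bool = False,
    skip_step3: bool = False,
    max_conflicts: int = 0,
    one_to_one: bool = False,
    rules: Optional[list[EliminationRule]] = None,
    compute_metrics: bool = True,
    index: Optional[CandidateIndex] = None,
) -> LinkageResult:
    """Run the full pipeline and return a reconciled LinkageResult.

    ``skip_step3`` reports the pre-definitive state (no elimination);
    ``one_to_one`` demotes every set of retained pairs sharing a target back
    to ambiguity instead of merely counting the collisions.
    """
    book = book or default_book()
    if index is None:
        index = build_index(target, book)
    outcomes = step1_link(source, target, index, book, max_conflicts=max_conflicts)
    no_cand = [o.source_id for o in outcomes if o.outcome_class == CLASS_NO_CANDIDATE]
    uniques = [o for o in outcomes if o.outcome_class == CLASS_UNIQUE]
    ambiguous = [o for o in outcomes if o.outcome_class == CLASS_AMBIGUOUS]

    pairs: list[LinkedPair] = [
        LinkedPair(o.source_id, o.candidate_ids[0], o.best_signature) for o in uniques
    ]
    if skip_step2 or not ambiguous:
        step2 = Step2Result(resolved=[], still_ambiguous=list(ambiguous), log=pd.DataFrame(
            columns=["source_id", "target_id", "hits", "n_hits"]))
    else:
        step2 = step2_resolve(ambiguous, source, target, book)
    for outcome, target_id, hit in step2.resolved:
        src = source.by_id[outcome.source_id]
        from .signatures import agreement_signature

        sig = agreement_signature(src, target.by_id[target_id], book)
        pairs.append(
            LinkedPair(
                outcome.source_id,
                target_id,
                sig,
                step2_resolved=True,
                checking_hits=hit,
            )
        )
    still_ambiguous = [o.source_id for o in step2.still_ambiguous]

    # many-sources-to-one-target collisions
    claims: dict[str, list[LinkedPair]] = {}
    for p in pairs:
        claims.setdefault(p.target_id, []).append(p)
    colliding = [ps for ps in claims.values() if len(ps) > 1]
    demoted: list[str] = []
    if one_to_one and colliding:
        drop = {p.source_id for ps in colliding for p in ps}
        demoted = sorted(drop)
        pairs = [p for p in pairs if p.source_id not in drop]
        colliding = []

    if skip_step3:
        step3 = Step3Result(retained=pairs, eliminated_groups=[])
    else:
        step3 = step3_filter(pairs, rules, book=book)
    retained = step3.retained

    if compute_metrics:
        for p in retained:
            if not p.step2_resolved:
                p.robustness = robustness(
                    p, source, target, index, book, max_conflicts=max_conflicts
                )
                p.checking_hits = evaluate_checking(
                    source.by_id[p.source_id], target.by_id[p.target_id], book.checking
                )
            p.quality = quality(p)

    n_collisions = sum(1 for ps in claims.values() if len(ps) > 1) if not one_to_one else 0
    return LinkageResult(
        book=book,
        outcomes=outcomes,
        pairs=retained,
        eliminated_groups=step3.eliminated_groups,
        still_ambiguous_ids=still_ambiguous,
        no_candidate_ids=no_cand,
        demoted_collision_ids=demoted,
        n_source=len(source),
        target_collisions=n_collisions,
        step2_log=step2.log,
        flags={
            "skip_step2": skip_step2,
            "skip_step3": skip_step3,
            "max_conflicts": max_conflicts,
            "one_to_one": one_to_one,
        },
        source=source,
    )
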