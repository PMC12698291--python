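"""Score linkage output against planted truth and build the report surfaces.

Only synthetic data carries ground truth, so precision/recall scoring lives
here next to the report tables a real run would also produce: matching-rate
breakdowns by origin, signature frequency tables with robustness order
statistics, the quality distribution, the death-date contribution audit, and
the paired-vs-nonpaired characteristics comparison used to discuss linkage
selection bias.

Undefined ratios are reported as ``None``/NaN (never 0).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._util import percentage
from .metrics import LinkedPair
from .pipeline import GROUPS, LinkageResult
from .records import MISSING, RecordSet
from .signatures import render_signature
from .simulate import TruthMap


@dataclass
class EvaluationReport:
    n_source: int
    n_pairs: int
    n_no_candidate: int
    n_ambiguous_final: int
    n_eliminated: int
    matching_rate_overall: float
    matching_rate_by_group: dict
    precision: Optional[float]
    recall: float
    f1: Optional[float]
    by_quality: dict  # Q -> {n, n_correct, precision}
    by_signature: dict  # signature string -> {n, n_correct, precision}
    death_date_audit: dict

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {str(k): clean(x) for k, x in v.items()}
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return {k: clean(v) for k, v in sorted(self.__dict__.items())}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _safe_ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def evaluate(result: LinkageResult, truth: TruthMap) -> EvaluationReport:
    """Precision = correct/retained, recall = correct/planted; strata on retained."""
    truth_ids = set(truth.mapping)
    source_ids = {o.source_id for o in result.outcomes}
    if truth_ids != source_ids:
        raise ValueError("truth map and linkage result cover different source ids")
    pairs = result.pairs
    correct = [p for p in pairs if truth.mapping.get(p.source_id) == p.target_id]
    precision = _safe_ratio(len(correct), len(pairs))
    recall = len(correct) / len(truth.mapping)
    f1 = (
        None
        if precision is None or precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )

    def stratify(key) -> dict:
        strata: dict = {}
        for p in pairs:
            k = key(p)
            s = strata.setdefault(k, {"n": 0, "n_correct": 0})
            s["n"] += 1
            s["n_correct"] += int(truth.mapping.get(p.source_id) == p.target_id)
        for s in strata.values():
            s["precision"] = _safe_ratio(s["n_correct"], s["n"])
        return dict(sorted(strata.items(), key=lambda kv: str(kv[0])))

    return EvaluationReport(
        n_source=result.n_source,
        n_pairs=result.n_pairs,
        n_no_candidate=result.n_no_candidate,
        n_ambiguous_final=result.n_ambiguous_final,
        n_eliminated=result.n_eliminated,
        matching_rate_overall=result.definitive_matching_rate,
        matching_rate_by_group=result.matching_rate_by_group(),
        precision=precision,
        recall=recall,
        f1=f1,
        by_quality=stratify(lambda p: p.quality),
        by_signature=stratify(lambda p: render_signature(p.signature, result.book)),
        death_date_audit=death_date_audit(pairs)._asdict(),
    )


# ---------------------------------------------------------------------------
# Report tables


def signature_frequency_table(pairs: list[LinkedPair], book) -> pd.DataFrame:
    """Signatures by descending pair count (ties broken by signature string),
    with robustness order statistics and cumulative share."""
    groups: dict[str, list[LinkedPair]] = {}
    for p in pairs:
        groups.setdefault(render_signature(p.signature, book), []).append(p)
    rows = []
    for s in sorted(groups, key=lambda k: (-len(groups[k]), k)):
        members = groups[s]
        rs = [p.robustness for p in members if p.robustness is not None]
        rows.append(
            {
                "signature": s,
                "n": len(members),
                "r_min": min(rs) if rs else np.nan,
                "r_median": float(np.median(rs)) if rs else np.nan,
                "r_max": max(rs) if rs else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=["signature", "n", "r_min", "r_median", "r_max"])
    total = df["n"].sum()
    df["cumulative_share"] = df["n"].cumsum() / total if total else np.nan
    return df


from collections import namedtuple  # noqa: E402

DeathAudit = namedtuple("DeathAudit", ["n_with_death", "n_robust", "pct_robust"])


def death_date_audit(pairs: list[LinkedPair]) -> DeathAudit:
    """How often the death date reinforced (R > 0) rather than carried a pair.

    Counts retained pairs whose signature includes the death-date slot ``D``
    and, among them, those whose robustness is positive (the pair would
    survive dropping any one variable, the death date included).
    """
    with_d = [p for p in pairs if "D" in p.signature.present]
    robust = [p for p in with_d if p.robustness is not None and p.robustness > 0]
    pct = percentage(len(robust), len(with_d), 1) if with_d else None
    return DeathAudit(len(with_d), len(robust), pct)


def compare_paired_unpaired(
    source: RecordSet,
    result: LinkageResult,
    reference_field: str = "surgery_date",
) -> pd.DataFrame:
    """Characteristics of paired vs nonpaired source records by origin and sex.

    Age is computed at the reference event date (surgery by default); counts
    and row percents are within (group, sex); age statistics ignore records
    whose reference or birth date is missing.
    """
    paired_ids = {p.source_id for p in result.pairs}
    rows = []
    for gname, subsets in GROUPS.items():
        members = [r for r in source.records if (r.subset or "both") in subsets]
        for sexval in sorted({r.raw.get("sex") for r in members if r.raw.get("sex")}):
            sex_members = [r for r in members if r.raw.get("sex") == sexval]
            n_sex = len(sex_members)
            for status, sel in (
                ("paired", [r for r in sex_members if r.record_id in paired_ids]),
                ("nonpaired", [r for r in sex_members if r.record_id not in paired_ids]),
            ):
                ages = []
                for r in sel:
                    ref = r.raw.get(reference_field, MISSING)
                    birth = r.raw.get("birth_date", MISSING)
                    if ref is not MISSING and birth is not MISSING:
                        ages.append(int((ref - birth).days / 365.25))
                a = np.asarray(ages, dtype=float)
                rows.append(
                    {
                        "group": gname,
                        "sex": sexval,
                        "status": status,
                        "n": len(sel),
                        "pct": percentage(len(sel), n_sex, 1) if n_sex else np.nan,
                        "age_mean": a.mean() if len(a) else np.nan,
                        "age_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
                        "age_min": a.min() if len(a) else np.nan,
                        "age_max": a.max() if len(a) else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["group", "sex", "status", "n", "pct", "age_mean", "age_sd", "age_min", "age_max"],
    )
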