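"""Record store: read, normalize and index the source/target tables.

A :class:`Record` carries, for every chaining variable of the book, either a
normalized comparable value or the explicit missing marker (``None``), plus
the normalized raw fields needed by the checking comparators.  Coarse
variables are derived from fine ones when absent (department from the town
prefix), and overwritten when inconsistent, so the granularity hierarchy
(town agree ⇒ department agree) holds on every loaded record.

Rows with unparseable dates are quarantined — collected with their row number
on the returned :class:`RecordSet` — and linkage proceeds on clean rows.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from ._util import percentage
from .book import (
    KIND_CATEGORICAL,
    KIND_CATEGORICAL_AT_DATE,
    KIND_DATE,
    ChainingVariableSpec,
    LinkageBook,
)

MISSING = None
DEFAULT_SENTINELS = frozenset({"", "na", "nan", "unk", "none", "null"})

SUBSET_BOTH = "both"
SUBSET_CLINICAL = "clinical_only"
SUBSET_PATHOLOGICAL = "pathological_only"
SUBSETS = (SUBSET_BOTH, SUBSET_CLINICAL, SUBSET_PATHOLOGICAL)


class RecordError(ValueError):
    """Fatal problem with an input table (e.g. missing id column)."""


@dataclass
class Record:
    """One normalized row of either database."""

    record_id: str
    origin: str  # "source" | "target"
    values: dict[str, object]  # chaining code -> normalized value or None
    raw: dict[str, object]  # normalized raw fields (checking comparators, reports)
    subset: Optional[str] = None  # source records only

    def defined(self, code: str) -> bool:
        return self.values.get(code) is not MISSING


@dataclass
class RecordSet:
    records: list[Record]
    role: str  # "source" | "target"
    schema_fingerprint: str = ""
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise RecordError(f"duplicate record ids in {self.role} set")
        self.by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


# ---------------------------------------------------------------------------
# Normalization


def _norm_token(value, sentinels=DEFAULT_SENTINELS):
    if value is None:
        return MISSING
    if isinstance(value, float) and math.isnan(value):
        return MISSING
    s = str(value).strip()
    if s.lower() in sentinels:
        return MISSING
    return s.lower()


def parse_date(value, sentinels=DEFAULT_SENTINELS) -> Optional[_dt.date]:
    """ISO-8601 calendar date or missing; invalid dates raise ValueError."""
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    if isinstance(value, (_dt.datetime, pd.Timestamp)):
        return value.date()
    tok = _norm_token(value, sentinels)
    if tok is MISSING:
        return MISSING
    return _dt.date.fromisoformat(tok)


def apply_transform(value, transform: str):
    if value is MISSING:
        return MISSING
    if transform == "none":
        return value
    if transform == "year_month":
        return (value.year, value.month)
    if transform == "year":
        return value.year
    if transform == "prefix2":
        return str(value)[:2]
    raise ValueError(f"unknown transform {transform!r}")


def _is_date_field(book: LinkageBook, fld: str, role: str) -> bool:
    for v in book.chaining:
        fields = v.source_fields if role == "source" else v.target_fields
        if fld in fields:
            if v.kind == KIND_DATE:
                return True
            if v.kind == KIND_CATEGORICAL_AT_DATE and fld == fields[-1]:
                return True
            if v.transform_of(fld) in ("year_month", "year"):
                return True
    for v in book.checking:
        fields = v.source_fields if role == "source" else v.target_fields
        if v.comparator == "event_within_window" and fld in fields:
            return True
    # date-suffixed columns are parsed as dates for the raw store (age reports)
    return fld.endswith("_date")


def _chaining_value(spec: ChainingVariableSpec, raw: dict, role: str):
    fields = spec.source_fields if role == "source" else spec.target_fields
    vals = []
    for f in fields:
        v = raw.get(f, MISSING)
        t = spec.transform_of(f)
        v = apply_transform(v, t)
        if v is MISSING:
            return MISSING
        vals.append(v)
    if spec.kind == KIND_DATE:
        return vals[0]
    if spec.kind == KIND_CATEGORICAL_AT_DATE:
        cat = tuple(vals[:-1]) if len(vals) > 2 else vals[0]
        return (cat, vals[-1])
    return tuple(vals) if len(vals) > 1 else vals[0]


def normalize_record(
    row: dict,
    book: LinkageBook,
    role: str,
    record_id: str,
    sentinels=DEFAULT_SENTINELS,
) -> Record:
    """Build a Record from a raw row mapping (may raise ValueError on bad dates)."""
    fields = book.source_columns() if role == "source" else book.target_columns()
    raw: dict[str, object] = {}
    for f in fields:
        if f not in row:
            continue
        if _is_date_field(book, f, role):
            raw[f] = parse_date(row[f], sentinels)
        else:
            raw[f] = _norm_token(row[f], sentinels)
    for f in ("birth_date",):  # always useful for reports
        if f in row and f not in raw:
            raw[f] = parse_date(row[f], sentinels)
    # derive coarse raw fields from fine ones; fine value wins on inconsistency
    for spec in book.chaining:
        if spec.derive is None or spec.coarsening_of is None:
            continue
        src_field, transform = spec.derive
        own = (spec.source_fields if role == "source" else spec.target_fields)[0]
        fine_val = raw.get(src_field, MISSING)
        if fine_val is not MISSING:
            raw[own] = apply_transform(fine_val, transform)
    values = {spec.code: _chaining_value(spec, raw, role) for spec in book.chaining}
    subset = _norm_token(row.get("subset"), sentinels) if role == "source" else None
    return Record(record_id=record_id, origin=role, values=values, raw=raw, subset=subset)


def load_records(
    data,
    book: LinkageBook,
    role: str,
    id_column: str = "patient_id",
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
) -> RecordSet:
    """Load a delimited-text table (or DataFrame) into a normalized RecordSet.

    Comma is the default delimiter; tab-separated files are detected from the
    header line.  Rows whose dates do not parse are excluded and reported in
    ``RecordSet.row_errors`` with their (1-based, header-exclusive) row number.
    """
    if role not in ("source", "target"):
        raise ValueError("role must be 'source' or 'target'")
    sentinels = frozenset(s.lower() for s in sentinels)
    if isinstance(data, pd.DataFrame):
        frame = data
    else:
        path = Path(data)
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in frame.columns:
        raise RecordError(f"mandatory id column {id_column!r} absent from {role} table")
    records: list[Record] = []
    errors: list[tuple[int, str]] = []
    cols = list(frame.columns)
    for i, row_vals in enumerate(frame.itertuples(index=False, name=None), start=1):
        row = dict(zip(cols, row_vals))
        rid = str(row[id_column]).strip()
        try:
            records.append(normalize_record(row, book, role, rid, sentinels))
        except ValueError as exc:
            errors.append((i, f"{rid}: {exc}"))
    fp = hashlib.sha1(",".join(sorted(cols)).encode()).hexdigest()[:12]
    return RecordSet(records=records, role=role, schema_fingerprint=fp, row_errors=errors)


# ---------------------------------------------------------------------------
# Missingness report


def missingness_report(
    rs: RecordSet, book: LinkageBook, by_subset: bool = True
) -> pd.DataFrame:
    """Per-(subset, variable) missing counts and percents for the chaining slots.

    Percentages are computed against the subset total and rounded half-up to
    two decimals.
    """
    if not rs.records:
        raise RecordError("missingness report on empty record set")
    groups: dict[str, list[Record]] = {}
    if by_subset and rs.role == "source":
        for r in rs.records:
            groups.setdefault(r.subset or "unlabelled", []).append(r)
    groups["all"] = list(rs.records)
    rows = []
    for label in sorted(groups):
        recs = groups[label]
        total = len(recs)
        for spec in book.chaining:
            n_missing = sum(1 for r in recs if not r.defined(spec.code))
            rows.append(
                {
                    "subset": label,
                    "variable": spec.code,
                    "n_missing": n_missing,
                    "pct_missing": percentage(n_missing, total, 2),
                    "subset_total": total,
                }
            )
    return pd.DataFrame(rows)
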