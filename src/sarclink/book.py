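"""Linkage management book: the configuration that drives the whole engine.

The *book* declares the chaining-variable alphabet (the letters that make up a
signature, ordered so each letter owns one fixed slot in the rendered string),
the granularity hierarchy between fine and coarse variables (sex + birth
month/year ``S`` vs sex + birth year ``s``; town of residency ``L`` vs
department ``l``), the date-tolerance windows that absorb discrepancies between
the two record systems, the checking variables used only for disambiguation,
and the eligibility thresholds for that disambiguation step.

The book is data, not code: it ships as an annotated YAML file
(``data/default_book.yaml``) and everything in it can be overridden.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

KIND_CATEGORICAL = "categorical"
KIND_DATE = "date"
KIND_CATEGORICAL_AT_DATE = "categorical_at_date"
KINDS = {KIND_CATEGORICAL, KIND_DATE, KIND_CATEGORICAL_AT_DATE}

DIR_SYMMETRIC = "symmetric"
DIR_TARGET_NOT_AFTER = "target_not_after_source"
DIR_TARGET_NOT_BEFORE = "target_not_before_source"
DIRECTIONS = {DIR_SYMMETRIC, DIR_TARGET_NOT_AFTER, DIR_TARGET_NOT_BEFORE}

CMP_EVENT_WINDOW = "event_within_window"
CMP_CODE_MAPPING = "code_mapping_agreement"
COMPARATORS = {CMP_EVENT_WINDOW, CMP_CODE_MAPPING}

# field transforms applicable when normalizing / deriving values
TRANSFORMS = {"none", "year_month", "year", "prefix2"}


class BookError(ValueError):
    """Raised when a linkage book fails to parse or validate."""


@dataclass(frozen=True)
class ChainingVariableSpec:
    """One chaining variable (one slot of the signature alphabet).

    ``kind`` controls comparison semantics:

    * ``categorical`` — values agree iff equal (tuples of fields, possibly
      projected through ``transforms``, e.g. birth date to (year, month)).
    * ``date`` — a single calendar date; values agree iff the target date
      falls inside the tolerance window around the source date.
    * ``categorical_at_date`` — a category anchored at an event date (the
      last declared field is the date); agreement requires category equality
      AND date agreement.

    A coarse variable declares the fine variable it summarizes through
    ``coarsening_of`` and, when its own column may be absent, how to derive
    itself from one of the fine variable's raw fields through ``derive``.
    """

    code: str
    kind: str
    source_fields: tuple[str, ...]
    target_fields: tuple[str, ...]
    description: str = ""
    tolerance_days: int = 0
    tolerance_direction: str = DIR_SYMMETRIC
    coarsening_of: Optional[str] = None
    transforms: tuple[tuple[str, str], ...] = ()  # (field, transform) pairs
    derive: Optional[tuple[str, str]] = None  # (fine raw field, transform)

    @property
    def is_event(self) -> bool:
        """True for variables carrying an event date (the date-bearing kinds)."""
        return self.kind in (KIND_DATE, KIND_CATEGORICAL_AT_DATE)

    @property
    def date_field_source(self) -> Optional[str]:
        if self.kind == KIND_DATE:
            return self.source_fields[0]
        if self.kind == KIND_CATEGORICAL_AT_DATE:
            return self.source_fields[-1]
        return None

    @property
    def date_field_target(self) -> Optional[str]:
        if self.kind == KIND_DATE:
            return self.target_fields[0]
        if self.kind == KIND_CATEGORICAL_AT_DATE:
            return self.target_fields[-1]
        return None

    def transform_of(self, fld: str) -> str:
        for f, t in self.transforms:
            if f == fld:
                return t
        return "none"

    def window(self, source_ordinal: int) -> tuple[int, int]:
        """Inclusive [lo, hi] range of target date ordinals that agree."""
        t = self.tolerance_days
        if self.tolerance_direction == DIR_SYMMETRIC:
            return source_ordinal - t, source_ordinal + t
        if self.tolerance_direction == DIR_TARGET_NOT_AFTER:
            return source_ordinal - t, source_ordinal
        return source_ordinal, source_ordinal + t


@dataclass(frozen=True)
class CheckingVariableSpec:
    """An auxiliary comparator used only to disambiguate multiple candidates.

    ``event_within_window``: the target shows the declared event within
    ``window_days`` *after* the source's indication date (a planned treatment
    being followed through).  ``code_mapping_agreement``: the target's
    diagnosis code maps, via a two-column ``code,label`` table, to the
    source's category combination (fields joined with ``/``).
    """

    code: str
    comparator: str
    source_fields: tuple[str, ...]
    target_fields: tuple[str, ...]
    description: str = ""
    window_days: int = 0
    mapping_table_path: Optional[str] = None

    _mapping_cache: dict = field(default_factory=dict, compare=False, hash=False)

    def load_mapping(self) -> dict[str, str]:
        """Load (and cache) the code→label table; error if unavailable."""
        if self.comparator != CMP_CODE_MAPPING:
            raise BookError(f"checking variable {self.code!r} has no mapping table")
        if "map" not in self._mapping_cache:
            path = self.mapping_table_path
            if path is None:
                raise BookError(
                    f"checking variable {self.code!r}: mapping table required "
                    "for code_mapping_agreement but none configured"
                )
            if path.startswith("packaged:"):
                name = path.split(":", 1)[1]
                text = (
                    importlib.resources.files("sarclink").joinpath("data", name).read_text()
                )
            else:
                p = Path(path)
                if not p.exists():
                    raise BookError(
                        f"checking variable {self.code!r}: mapping table {path} not found"
                    )
                text = p.read_text()
            mapping: dict[str, str] = {}
            for i, line in enumerate(text.splitlines()):
                line = line.strip()
                if not line or (i == 0 and line.lower().startswith("code")):
                    continue
                code, _, label = line.partition(",")
                mapping[code.strip().lower()] = label.strip().lower()
            self._mapping_cache["map"] = mapping
        return self._mapping_cache["map"]


@dataclass(frozen=True)
class LinkageBook:
    """Validated linkage configuration; slot order of ``chaining`` is the alphabet."""

    chaining: tuple[ChainingVariableSpec, ...]
    checking: tuple[CheckingVariableSpec, ...]
    step2_min_signature: int = 5
    step2_max_missing: int = 2

    @property
    def alphabet(self) -> str:
        return "".join(v.code for v in self.chaining)

    @property
    def slots(self) -> dict[str, int]:
        return {v.code: i for i, v in enumerate(self.chaining)}

    @property
    def by_code(self) -> dict[str, ChainingVariableSpec]:
        return {v.code: v for v in self.chaining}

    @property
    def event_codes(self) -> frozenset[str]:
        return frozenset(v.code for v in self.chaining if v.is_event)

    def bitmask(self, codes) -> int:
        slots = self.slots
        m = 0
        for c in codes:
            m |= 1 << slots[c]
        return m

    @property
    def event_bitmask(self) -> int:
        return self.bitmask(self.event_codes)

    def source_columns(self) -> list[str]:
        cols: list[str] = []
        for v in self.chaining:
            cols.extend(v.source_fields)
        for v in self.checking:
            cols.extend(v.source_fields)
        seen: list[str] = []
        for c in cols:
            if c not in seen:
                seen.append(c)
        return seen

    def target_columns(self) -> list[str]:
        cols: list[str] = []
        for v in self.chaining:
            cols.extend(v.target_fields)
        for v in self.checking:
            cols.extend(v.target_fields)
        seen: list[str] = []
        for c in cols:
            if c not in seen:
                seen.append(c)
        return seen

    def validate(self) -> None:
        if not self.chaining:
            raise BookError("a linkage book must declare at least one chaining variable")
        codes = [v.code for v in self.chaining]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise BookError(f"duplicate chaining code(s): {dup}")
        check_codes = [v.code for v in self.checking]
        if len(set(check_codes)) != len(check_codes):
            raise BookError("duplicate checking code")
        overlap = set(codes) & set(check_codes)
        if overlap:
            raise BookError(f"checking codes must be disjoint from chaining: {sorted(overlap)}")
        by_code = self.by_code
        for v in self.chaining:
            if v.kind not in KINDS:
                raise BookError(f"{v.code}: unknown kind {v.kind!r}")
            if v.tolerance_direction not in DIRECTIONS:
                raise BookError(f"{v.code}: unknown tolerance direction {v.tolerance_direction!r}")
            if v.tolerance_days < 0:
                raise BookError(f"{v.code}: tolerance_days must be non-negative")
            if v.tolerance_days != 0 and not v.is_event:
                raise BookError(f"{v.code}: tolerance_days only allowed on date kinds")
            if not v.source_fields or not v.target_fields:
                raise BookError(f"{v.code}: source/target fields must be declared")
            for _, t in v.transforms:
                if t not in TRANSFORMS:
                    raise BookError(f"{v.code}: unknown transform {t!r}")
            if v.coarsening_of is not None:
                fine = by_code.get(v.coarsening_of)
                if fine is None:
                    raise BookError(
                        f"{v.code}: coarsening_of references unknown code {v.coarsening_of!r}"
                    )
                subset = set(v.source_fields) <= set(fine.source_fields)
                derives = v.derive is not None and v.derive[0] in fine.source_fields
                if not (subset or derives):
                    raise BookError(
                        f"{v.code}: coarse variable fields must project from {fine.code}'s "
                        "fields (field subset or a derive declaration)"
                    )
            if v.derive is not None and v.derive[1] not in TRANSFORMS:
                raise BookError(f"{v.code}: unknown derive transform {v.derive[1]!r}")
        for v in self.checking:
            if v.comparator not in COMPARATORS:
                raise BookError(f"{v.code}: unknown comparator {v.comparator!r}")
            if v.window_days < 0:
                raise BookError(f"{v.code}: window_days must be non-negative")
            if v.comparator == CMP_CODE_MAPPING and v.mapping_table_path is None:
                raise BookError(f"{v.code}: code_mapping_agreement requires a mapping table")
            if v.comparator == CMP_EVENT_WINDOW and v.mapping_table_path is not None:
                raise BookError(f"{v.code}: mapping table only valid for code_mapping_agreement")
        if self.step2_min_signature < 0 or self.step2_max_missing < 0:
            raise BookError("step-2 thresholds must be non-negative")


# ---------------------------------------------------------------------------
# (De)serialization


def _chaining_to_dict(v: ChainingVariableSpec) -> dict:
    d: dict = {
        "code": v.code,
        "description": v.description,
        "kind": v.kind,
        "source_fields": list(v.source_fields),
        "target_fields": list(v.target_fields),
    }
    if v.is_event:
        d["tolerance_days"] = v.tolerance_days
        d["tolerance_direction"] = v.tolerance_direction
    if v.coarsening_of is not None:
        d["coarsening_of"] = v.coarsening_of
    if v.transforms:
        d["transforms"] = {f: t for f, t in v.transforms}
    if v.derive is not None:
        d["derive"] = {"field": v.derive[0], "transform": v.derive[1]}
    return d


def _checking_to_dict(v: CheckingVariableSpec) -> dict:
    d: dict = {
        "code": v.code,
        "description": v.description,
        "comparator": v.comparator,
        "source_fields": list(v.source_fields),
        "target_fields": list(v.target_fields),
    }
    if v.comparator == CMP_EVENT_WINDOW:
        d["window_days"] = v.window_days
    if v.mapping_table_path is not None:
        d["mapping_table"] = v.mapping_table_path
    return d


def book_to_dict(book: LinkageBook) -> dict:
    return {
        "chaining": [_chaining_to_dict(v) for v in book.chaining],
        "checking": [_checking_to_dict(v) for v in book.checking],
        "step2": {
            "min_signature": book.step2_min_signature,
            "max_missing": book.step2_max_missing,
        },
    }


def _chaining_from_dict(d: dict) -> ChainingVariableSpec:
    transforms = tuple(sorted((d.get("transforms") or {}).items()))
    derive = None
    if "derive" in d and d["derive"] is not None:
        derive = (d["derive"]["field"], d["derive"].get("transform", "none"))
    return ChainingVariableSpec(
        code=str(d["code"]),
        description=d.get("description", ""),
        kind=d["kind"],
        source_fields=tuple(d["source_fields"]),
        target_fields=tuple(d["target_fields"]),
        tolerance_days=int(d.get("tolerance_days", 0)),
        tolerance_direction=d.get("tolerance_direction", DIR_SYMMETRIC),
        coarsening_of=d.get("coarsening_of"),
        transforms=transforms,
        derive=derive,
    )


def _checking_from_dict(d: dict) -> CheckingVariableSpec:
    return CheckingVariableSpec(
        code=str(d["code"]),
        description=d.get("description", ""),
        comparator=d["comparator"],
        source_fields=tuple(d["source_fields"]),
        target_fields=tuple(d["target_fields"]),
        window_days=int(d.get("window_days", 0)),
        mapping_table_path=d.get("mapping_table"),
    )


def book_from_dict(data: dict) -> LinkageBook:
    if not isinstance(data, dict) or "chaining" not in data:
        raise BookError("book must be a mapping with a 'chaining' list")
    step2 = data.get("step2") or {}
    book = LinkageBook(
        chaining=tuple(_chaining_from_dict(d) for d in (data.get("chaining") or [])),
        checking=tuple(_checking_from_dict(d) for d in (data.get("checking") or [])),
        step2_min_signature=int(step2.get("min_signature", 5)),
        step2_max_missing=int(step2.get("max_missing", 2)),
    )
    book.validate()
    return book


def load_book(path) -> LinkageBook:
    """Parse + validate a YAML linkage book; relative mapping paths resolve
    against the book file's directory."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # report the offending line
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise BookError(f"malformed book {path}{where}: {exc}") from exc
    book = book_from_dict(data)
    resolved = []
    for v in book.checking:
        p = v.mapping_table_path
        if p and not p.startswith("packaged:") and not Path(p).is_absolute():
            v = replace(v, mapping_table_path=str((path.parent / p)))
        resolved.append(v)
    return replace(book, checking=tuple(resolved))


def save_book(book: LinkageBook, path) -> None:
    """Serialize a book to YAML; load→save→load round-trips to an equal book
    and a second save is byte-identical."""
    Path(path).write_text(yaml.safe_dump(book_to_dict(book), sort_keys=False))


def default_book() -> LinkageBook:
    """The shipped 10-slot book (alphabet ``SsDLlCFRMO``, checking ``decr``)."""
    text = (
        importlib.resources.files("sarclink").joinpath("data", "default_book.yaml").read_text()
    )
    return book_from_dict(yaml.safe_load(text))


def validate_schema(book: LinkageBook, source_columns, target_columns) -> list[str]:
    """Check that every declared field exists in the given schemas.

    Returns diagnostics (one per missing field), empty on success.
    """
    diags: list[str] = []
    src = set(source_columns)
    tgt = set(target_columns)
    for v in list(book.chaining) + list(book.checking):
        for f in v.source_fields:
            if f not in src:
                diags.append(f"variable {v.code}: source column {f!r} missing")
        for f in v.target_fields:
            if f not in tgt:
                diags.append(f"variable {v.code}: target column {f!r} missing")
    return diags
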