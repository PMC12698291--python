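from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sarclink as sl
from sarclink.simulate import SOURCE_COLUMNS, TARGET_COLUMNS


@pytest.fixture(scope="session")
def book():
    return sl.default_book()


def make_source(book, rows):
    """Build a source RecordSet from partial row dicts."""
    frame = pd.DataFrame(
        [{c: row.get(c, "") for c in SOURCE_COLUMNS} for row in rows]
    )
    rs = sl.load_records(frame, book, "source")
    assert not rs.row_errors, rs.row_errors
    return rs


def make_target(book, rows):
    frame = pd.DataFrame(
        [{c: row.get(c, "") for c in TARGET_COLUMNS} for row in rows]
    )
    rs = sl.load_records(frame, book, "target")
    assert not rs.row_errors, rs.row_errors
    return rs


# A fully-defined prototype patient used by many constructed fixtures.
PROTO_SOURCE = dict(
    patient_id="s0",
    subset="both",
    sex="F",
    birth_date="1962-07-14",
    death_date="2016-09-02",
    town_code="69001",
    dept_code="69",
    tumor_type="soft tissue",
    tumor_site="limb",
    surgery_date="2015-03-10",
    facility_code="FIN0001",
    resection_date="2015-03-12",
    biopsy_date="2015-02-20",
)
PROTO_TARGET = dict(
    patient_id="t0",
    sex="F",
    birth_date="1962-07-14",
    death_date="2016-09-02",
    town_code="69001",
    dept_code="69",
    tumor_type="soft tissue",
    stay_start_date="2015-03-08",
    facility_code="FIN0001",
    resection_date="2015-03-12",
    biopsy_date="2015-02-20",
)


def random_instance(seed, n_source=12, n_target=120):
    """High-collision random tables over deliberately small value domains.

    Small domains (two sexes, three birth years, five towns, dates packed
    into a 40-day span against 30-day tolerance windows) force heavy
    candidate overlap, ambiguity and conflicts — a stress instance for
    index-vs-exhaustive-scan equivalence.
    """
    rng = np.random.default_rng(seed)
    book = sl.default_book()

    def dates(n, lo, span):
        out = []
        for present, off in zip(rng.random(n) < 0.7, rng.integers(0, span, n)):
            d = pd.Timestamp("2015-03-01") + pd.Timedelta(days=int(lo + off))
            out.append(d.date().isoformat() if present else "")
        return out

    def common(n):
        return dict(
            sex=rng.choice(["f", "m", ""], n, p=[0.45, 0.45, 0.10]),
            birth_date=[
                f"{rng.choice([1950, 1951, 1952])}-{rng.integers(1, 4):02d}-01"
                if rng.random() < 0.9
                else ""
                for _ in range(n)
            ],
            town_code=rng.choice(["01001", "01002", "02001", "02002", "03001", ""], n),
            tumor_type=rng.choice(["soft tissue", "bone", ""], n, p=[0.5, 0.4, 0.1]),
            death_date=dates(n, 300, 40),
            resection_date=dates(n, 2, 20),
            biopsy_date=dates(n, -30, 20),
        )

    c = common(n_source)
    src = pd.DataFrame(
        {
            "patient_id": [f"s{i}" for i in range(n_source)],
            "subset": "both",
            **c,
            "dept_code": "",
            "tumor_site": rng.choice(["limb", "trunk"], n_source),
            "surgery_date": dates(n_source, 0, 40),
            "facility_code": rng.choice(["fa", "fb", ""], n_source),
            "chemo_indication_date": dates(n_source, 10, 30),
            "radio_indication_date": dates(n_source, 10, 30),
            "reexcision_indication_date": "",
        }
    )[SOURCE_COLUMNS]
    c = common(n_target)
    tgt = pd.DataFrame(
        {
            "patient_id": [f"t{i}" for i in range(n_target)],
            **c,
            "dept_code": "",
            "stay_start_date": dates(n_target, -10, 50),
            "facility_code": rng.choice(["fa", "fb", ""], n_target),
            "chemo_date": dates(n_target, 30, 120),
            "radio_date": dates(n_target, 30, 120),
            "reexcision_date": "",
            "icd10_code": rng.choice(["c49.1", "c40.0", ""], n_target),
        }
    )[TARGET_COLUMNS]
    return sl.load_records(src, book, "source"), sl.load_records(tgt, book, "target"), book
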