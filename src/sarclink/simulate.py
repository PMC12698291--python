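"""Synthetic source/target registry pairs with planted ground truth.

The generator emulates the data landscape the linkage engine assumes: a
clinical registry (the *source*) whose records split into three subsets —
present in both the clinical and pathological bases, clinical-only,
pathological-only — embedded in a much larger administrative database (the
*target*) of cancer-surgery patients.  Each source record has exactly one
true counterpart in the target; the rest of the target is background noise
drawn from the same demographic and event-date distributions, plus *decoys*
that clone a true counterpart's demographic slots (and, by default, its
surgery stay) while differing on at least one other event date — the lever
that creates genuine ambiguity for the disambiguation step.

Structured differences between the two systems are reproduced:

* per-variable, per-subset missingness on the source side (pathological-only
  records locate patients and their surgery much less often);
* date discrepancies: the administrative side stores the hospital-stay start
  (a non-negative delay before the surgery date), while death and sampling
  dates wobble symmetrically;
* checking-variable structure: treatment indications on the source are
  followed through in the true counterpart's care pathway with a configured
  probability, and the stay's diagnosis code maps to the tumor type/site
  with a configured consistency.

Everything is deterministic given the seed, and every corruption applied to
a planted pair is written to a log that exactly explains any disagreement
between its two records.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .book import default_book
from .records import RecordSet, load_records

_EPOCH_BIRTH = (_dt.date(1930, 1, 1).toordinal(), _dt.date(2009, 12, 31).toordinal())
_EPOCH_SURGERY = (_dt.date(2010, 1, 1).toordinal(), _dt.date(2017, 12, 31).toordinal())
_LAST_DAY = _dt.date(2018, 12, 31).toordinal()

TYPES = ("soft tissue", "bone", "viscera")
TYPE_PROBS = (0.60, 0.25, 0.15)
SITES_BY_TYPE = {
    "soft tissue": ("head and neck", "limb", "thorax", "abdomen", "pelvis", "trunk", "other"),
    "bone": ("limb", "head and neck", "trunk", "pelvis", "other"),
    "viscera": ("retroperitoneum", "abdomen", "pelvis"),
}

SOURCE_COLUMNS = [
    "patient_id", "subset", "sex", "birth_date", "death_date", "town_code",
    "dept_code", "tumor_type", "tumor_site", "surgery_date", "facility_code",
    "resection_date", "biopsy_date", "chemo_indication_date",
    "radio_indication_date", "reexcision_indication_date",
]
TARGET_COLUMNS = [
    "patient_id", "sex", "birth_date", "death_date", "town_code", "dept_code",
    "tumor_type", "stay_start_date", "facility_code", "resection_date",
    "biopsy_date", "chemo_date", "radio_date", "reexcision_date", "icd10_code",
]

# default source-side missingness by (variable, subset); the pathological-only
# subset locates patients and their surgery far less often than the clinical
# side, which is what drives the per-subset matching-rate ordering
DEFAULT_MISSINGNESS = {
    "town_code": {"both": 0.0759, "clinical_only": 0.0759, "pathological_only": 0.1545},
    "dept_code": {"both": 0.0453, "clinical_only": 0.0453, "pathological_only": 0.1213},
    "surgery_date": {"both": 0.0088, "clinical_only": 0.0088, "pathological_only": 0.30},
    "facility_code": {"both": 0.789, "clinical_only": 0.789, "pathological_only": 1.0},
    "tumor_type": {"both": 0.0, "clinical_only": 0.0, "pathological_only": 0.0083},
    "resection_date": {"both": 0.05, "clinical_only": 0.40, "pathological_only": 0.05},
    "biopsy_date": {"both": 0.0, "clinical_only": 0.80, "pathological_only": 0.0},
    "death_date": {"both": 0.10, "clinical_only": 0.10, "pathological_only": 0.10},
}
DEFAULT_TARGET_MISSINGNESS = {"town_code": 0.03, "death_date": 0.05}
DEFAULT_JITTER = {
    "stay_start_date": ("geometric_delay", 4.0),
    "death_date": ("uniform_shift", 30.0),
    "resection_date": ("uniform_shift", 5.0),
    "biopsy_date": ("uniform_shift", 5.0),
}
DEFAULT_CHECKING_RATES = {
    "indication_rate": 0.35,
    "follow_rate": 0.80,
    "icd10_consistency": 0.90,
    "background_event_rate": 0.30,
}


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    n_target: int = 50_000
    n_source: int = 2_000
    subset_props: tuple[float, float, float] = (0.403, 0.174, 0.423)  # both/clin/path
    missingness: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISSINGNESS.items()})
    target_missingness: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_MISSINGNESS))
    date_jitter: dict = field(default_factory=lambda: dict(DEFAULT_JITTER))
    decoy_rate: float = 0.05
    decoy_profile: tuple[str, ...] = ("S", "s", "L", "l", "C", "O")
    checking_field_rates: dict = field(default_factory=lambda: dict(DEFAULT_CHECKING_RATES))
    fraction_deceased: float = 0.30
    presence_resection: float = 0.80
    presence_biopsy: float = 0.85
    n_towns: int = 400
    n_depts: int = 40
    n_facilities: int = 60
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subset_props) - 1.0) > 1e-9:
            raise ConfigError("subset proportions must sum to 1")
        if not 0 < self.n_source <= self.n_target:
            raise ConfigError("need 0 < n_source <= n_target")
        rates = [self.decoy_rate, self.fraction_deceased, self.presence_resection,
                 self.presence_biopsy, *self.checking_field_rates.values(),
                 *self.target_missingness.values()]
        for d in self.missingness.values():
            rates.extend(d.values())
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        for fam, _scale in self.date_jitter.values():
            if fam not in ("none", "uniform_shift", "geometric_delay"):
                raise ConfigError(f"unknown jitter family {fam!r}")
        if self.decoy_rate * self.n_source > self.n_target - self.n_source:
            raise ConfigError("decoy budget exceeds available target slots")

    def noiseless(self) -> "SimulationConfig":
        """Copy with zero missingness, zero jitter, zero decoys, all events present."""
        return SimulationConfig(
            n_target=self.n_target,
            n_source=self.n_source,
            subset_props=self.subset_props,
            missingness={v: {s: 0.0 for s in d} for v, d in self.missingness.items()},
            target_missingness={v: 0.0 for v in self.target_missingness},
            date_jitter={v: ("none", 0.0) for v in self.date_jitter},
            decoy_rate=0.0,
            decoy_profile=self.decoy_profile,
            checking_field_rates=dict(self.checking_field_rates),
            fraction_deceased=self.fraction_deceased,
            presence_resection=1.0,
            presence_biopsy=1.0,
            n_towns=self.n_towns,
            n_depts=self.n_depts,
            n_facilities=self.n_facilities,
            seed=self.seed,
        )


@dataclass
class TruthMap:
    mapping: dict[str, str]  # source_id -> target_id (injective, complete)
    corruption_log: pd.DataFrame  # side, record_id, variable, action, detail

    def validate(self, n_source: int) -> None:
        if len(self.mapping) != n_source:
            raise ConfigError("truth map must cover every source record")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ConfigError("truth map must be injective")


# ---------------------------------------------------------------------------


def _iso(ordinals, present) -> list[str]:
    return [
        _dt.date.fromordinal(int(o)).isoformat() if p else ""
        for o, p in zip(ordinals, present)
    ]


def _jitter(rng, cfg: SimulationConfig, variable: str, n: int) -> np.ndarray:
    """Signed day-shifts applied to the target copy of a planted date."""
    fam, scale = cfg.date_jitter.get(variable, ("none", 0.0))
    if fam == "none" or scale <= 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    if fam == "uniform_shift":
        s = int(scale)
        return rng.integers(-s, s + 1, size=n)
    # geometric_delay: non-negative delay, target date precedes the source date
    return -(rng.geometric(1.0 / scale, size=n) - 1)


def _zipf_probs(n: int) -> np.ndarray:
    p = 1.0 / np.arange(1, n + 1)
    return p / p.sum()


def generate_frames(cfg: SimulationConfig):
    """Return (source_df, target_df, truth_df, corruption_log_df)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.n_source
    rates = cfg.checking_field_rates

    towns = np.array(
        [f"{(i % cfg.n_depts) + 1:02d}{i // cfg.n_depts:03d}" for i in range(cfg.n_towns)]
    )
    town_probs = _zipf_probs(cfg.n_towns)
    facilities = np.array([f"fin{k:04d}" for k in range(cfg.n_facilities)])

    # ---- true entities -----------------------------------------------------
    subset = rng.choice(
        ["both", "clinical_only", "pathological_only"], size=ns, p=cfg.subset_props
    )
    sex = rng.choice(["f", "m"], size=ns)
    birth = rng.integers(_EPOCH_BIRTH[0], _EPOCH_BIRTH[1] + 1, size=ns)
    town_idx = rng.choice(cfg.n_towns, size=ns, p=town_probs)
    town = towns[town_idx]
    dept = np.array([t[:2] for t in town])
    ttype = rng.choice(TYPES, size=ns, p=TYPE_PROBS)
    site = np.array([rng.choice(SITES_BY_TYPE[t]) for t in ttype])
    surgery = rng.integers(_EPOCH_SURGERY[0], _EPOCH_SURGERY[1] + 1, size=ns)
    facility = rng.choice(facilities, size=ns)
    dead = rng.random(ns) < cfg.fraction_deceased
    death = np.minimum(surgery + rng.integers(30, 2000, size=ns), _LAST_DAY)
    has_resection = rng.random(ns) < cfg.presence_resection
    resection = surgery + rng.integers(0, 8, size=ns)
    has_biopsy = rng.random(ns) < cfg.presence_biopsy
    biopsy = surgery - rng.integers(7, 61, size=ns)
    has_ind = {k: rng.random(ns) < rates["indication_rate"] for k in ("chemo", "radio", "reexcision")}
    ind_date = {k: surgery + rng.integers(7, 31, size=ns) for k in ("chemo", "radio", "reexcision")}

    log_rows: list[dict] = []

    # ---- target counterparts ----------------------------------------------
    stay_shift = _jitter(rng, cfg, "stay_start_date", ns)
    stay = surgery + stay_shift
    death_shift = _jitter(rng, cfg, "death_date", ns)
    t_death = death + death_shift
    res_shift = _jitter(rng, cfg, "resection_date", ns)
    t_res = resection + res_shift
    bio_shift = _jitter(rng, cfg, "biopsy_date", ns)
    t_bio = biopsy + bio_shift
    for i in range(ns):
        if stay_shift[i]:
            log_rows.append(dict(side="target", idx=i, variable="stay_start_date",
                                 action="jittered", detail=int(stay_shift[i])))
        if dead[i] and death_shift[i]:
            log_rows.append(dict(side="target", idx=i, variable="death_date",
                                 action="jittered", detail=int(death_shift[i])))
        if has_resection[i] and res_shift[i]:
            log_rows.append(dict(side="target", idx=i, variable="resection_date",
                                 action="jittered", detail=int(res_shift[i])))
        if has_biopsy[i] and bio_shift[i]:
            log_rows.append(dict(side="target", idx=i, variable="biopsy_date",
                                 action="jittered", detail=int(bio_shift[i])))

    t_town_mask = rng.random(ns) < cfg.target_missingness.get("town_code", 0.0)
    t_death_mask = rng.random(ns) < cfg.target_missingness.get("death_date", 0.0)
    for i in np.flatnonzero(t_town_mask):
        log_rows.append(dict(side="target", idx=int(i), variable="town_code",
                             action="masked", detail=""))
    for i in np.flatnonzero(t_death_mask & dead):
        log_rows.append(dict(side="target", idx=int(i), variable="death_date",
                             action="masked", detail=""))

    followed = {k: rng.random(ns) < rates["follow_rate"] for k in ("chemo", "radio", "reexcision")}
    event_date = {k: ind_date[k] + rng.integers(7, 121, size=ns) for k in ("chemo", "radio", "reexcision")}

    from .book import default_book as _db  # mapping shipped with the default book

    map_spec = next(v for v in _db().checking if v.comparator == "code_mapping_agreement")
    mapping = map_spec.load_mapping()
    inv: dict[str, list[str]] = {}
    for code, label in mapping.items():
        inv.setdefault(label, []).append(code)
    all_codes = sorted(mapping)
    icd_ok = rng.random(ns) < rates["icd10_consistency"]
    icd = np.array(
        [
            sorted(inv.get(f"{t}/{s}", all_codes))[0] if ok else rng.choice(all_codes)
            for t, s, ok in zip(ttype, site, icd_ok)
        ]
    )

    counterpart = {
        "sex": sex.copy(),
        "birth": birth.copy(),
        "death": t_death,
        "has_death": dead & ~t_death_mask,
        "town": town.copy(),
        "has_town": ~t_town_mask,
        "dept": dept.copy(),
        "ttype": ttype.copy(),
        "stay": stay,
        "facility": facility.copy(),
        "resection": t_res,
        "has_resection": has_resection.copy(),
        "biopsy": t_bio,
        "has_biopsy": has_biopsy.copy(),
        "chemo": event_date["chemo"],
        "has_chemo": has_ind["chemo"] & followed["chemo"],
        "radio": event_date["radio"],
        "has_radio": has_ind["radio"] & followed["radio"],
        "reexcision": event_date["reexcision"],
        "has_reexcision": has_ind["reexcision"] & followed["reexcision"],
        "icd": icd,
    }

    # ---- decoys ------------------------------------------------------------
    n_decoys = int(rng.binomial(ns, cfg.decoy_rate)) if cfg.decoy_rate > 0 else 0
    decoy_of = rng.choice(ns, size=n_decoys) if n_decoys else np.empty(0, dtype=int)
    profile = set(cfg.decoy_profile)
    dec: dict[str, np.ndarray] = {}
    if n_decoys:
        share_demo = {"S", "s"} & profile
        share_town = {"L", "l"} & profile
        share_stay = {"C", "O", "F"} & profile
        dec["sex"] = sex[decoy_of] if share_demo else rng.choice(["f", "m"], n_decoys)
        dec["birth"] = (
            birth[decoy_of] if share_demo
            else rng.integers(_EPOCH_BIRTH[0], _EPOCH_BIRTH[1] + 1, n_decoys)
        )
        d_town_idx = rng.choice(cfg.n_towns, size=n_decoys, p=town_probs)
        dec["town"] = town[decoy_of] if share_town else towns[d_town_idx]
        dec["dept"] = np.array([t[:2] for t in dec["town"]])
        dec["has_town"] = np.ones(n_decoys, dtype=bool)
        dec["ttype"] = ttype[decoy_of] if "C" in profile else rng.choice(TYPES, n_decoys, p=TYPE_PROBS)
        dec["stay"] = (
            stay[decoy_of] if share_stay
            else rng.integers(_EPOCH_SURGERY[0], _EPOCH_SURGERY[1] + 1, n_decoys)
        )
        # guarantee >=1 differing event date: facility always fresh, resection/
        # biopsy shifted far outside any tolerance window or absent, no death
        dec["facility"] = rng.choice(facilities, n_decoys)
        if "F" in profile:
            dec["facility"] = facility[decoy_of]
        dec["has_death"] = np.zeros(n_decoys, dtype=bool)
        dec["death"] = np.zeros(n_decoys, dtype=np.int64)
        dec["has_resection"] = rng.random(n_decoys) < 0.5
        dec["resection"] = resection[decoy_of] + rng.integers(45, 300, n_decoys)
        dec["has_biopsy"] = rng.random(n_decoys) < 0.5
        dec["biopsy"] = biopsy[decoy_of] - rng.integers(45, 300, n_decoys)
        for k in ("chemo", "radio", "reexcision"):
            dec[f"has_{k}"] = rng.random(n_decoys) < rates["background_event_rate"]
            dec[k] = rng.integers(_EPOCH_SURGERY[0], _LAST_DAY + 1, n_decoys)
        dec["icd"] = rng.choice(all_codes, n_decoys)

    # ---- background --------------------------------------------------------
    nb = cfg.n_target - ns - n_decoys
    bg: dict[str, np.ndarray] = {}
    bg["sex"] = rng.choice(["f", "m"], nb)
    bg["birth"] = rng.integers(_EPOCH_BIRTH[0], _EPOCH_BIRTH[1] + 1, nb)
    b_town_idx = rng.choice(cfg.n_towns, size=nb, p=town_probs)
    bg["town"] = towns[b_town_idx]
    bg["dept"] = np.array([t[:2] for t in bg["town"]])
    bg["has_town"] = rng.random(nb) >= cfg.target_missingness.get("town_code", 0.0)
    bg["ttype"] = rng.choice(TYPES, nb, p=TYPE_PROBS)
    bg["stay"] = rng.integers(_EPOCH_SURGERY[0], _EPOCH_SURGERY[1] + 1, nb)
    bg["facility"] = rng.choice(facilities, nb)
    bg["has_death"] = rng.random(nb) < cfg.fraction_deceased
    bg["death"] = np.minimum(bg["stay"] + rng.integers(30, 2000, nb), _LAST_DAY)
    bg["has_resection"] = rng.random(nb) < 0.5
    bg["resection"] = bg["stay"] + rng.integers(0, 8, nb)
    bg["has_biopsy"] = rng.random(nb) < 0.5
    bg["biopsy"] = bg["stay"] - rng.integers(7, 61, nb)
    for k in ("chemo", "radio", "reexcision"):
        bg[f"has_{k}"] = rng.random(nb) < rates["background_event_rate"]
        bg[k] = bg["stay"] + rng.integers(7, 301, nb)
    bg_site = np.array([rng.choice(SITES_BY_TYPE[t]) for t in bg["ttype"]])
    bg_ok = rng.random(nb) < rates["icd10_consistency"]
    bg["icd"] = np.array(
        [
            sorted(inv.get(f"{t}/{s}", all_codes))[0] if ok else rng.choice(all_codes)
            for t, s, ok in zip(bg["ttype"], bg_site, bg_ok)
        ]
    )

    # ---- assemble target (shuffled) ---------------------------------------
    def block(d, n, kind):
        return pd.DataFrame(
            {
                "_kind": kind,
                "_idx": np.arange(n),
                "sex": d["sex"],
                "birth": d["birth"],
                "has_death": d["has_death"],
                "death": d["death"],
                "has_town": d["has_town"],
                "town": d["town"],
                "dept": d["dept"],
                "ttype": d["ttype"],
                "stay": d["stay"],
                "facility": d["facility"],
                "has_resection": d["has_resection"],
                "resection": d["resection"],
                "has_biopsy": d["has_biopsy"],
                "biopsy": d["biopsy"],
                "has_chemo": d["has_chemo"],
                "chemo": d["chemo"],
                "has_radio": d["has_radio"],
                "radio": d["radio"],
                "has_reexcision": d["has_reexcision"],
                "reexcision": d["reexcision"],
                "icd": d["icd"],
            }
        )

    blocks = [block(counterpart, ns, "pair")]
    if n_decoys:
        blocks.append(block(dec, n_decoys, "decoy"))
    if nb:
        blocks.append(block(bg, nb, "background"))
    tgt = pd.concat(blocks, ignore_index=True)
    perm = rng.permutation(len(tgt))
    tgt = tgt.iloc[perm].reset_index(drop=True)
    tgt["patient_id"] = [f"t{i:06d}" for i in range(len(tgt))]

    pair_rows = tgt["_kind"] == "pair"
    idx_to_tid = dict(zip(tgt.loc[pair_rows, "_idx"], tgt.loc[pair_rows, "patient_id"]))
    source_ids = [f"s{i:05d}" for i in range(ns)]
    truth = pd.DataFrame(
        {"source_id": source_ids, "target_id": [idx_to_tid[i] for i in range(ns)]}
    )
    if n_decoys:
        decoy_rows = tgt["_kind"] == "decoy"
        for di, tid in zip(tgt.loc[decoy_rows, "_idx"], tgt.loc[decoy_rows, "patient_id"]):
            log_rows.append(dict(side="target", idx=-1, variable="", action="decoy",
                                 detail=idx_to_tid[int(decoy_of[int(di)])], rid=tid))

    target_df = pd.DataFrame(
        {
            "patient_id": tgt["patient_id"],
            "sex": tgt["sex"],
            "birth_date": _iso(tgt["birth"], np.ones(len(tgt), bool)),
            "death_date": _iso(tgt["death"], tgt["has_death"]),
            "town_code": np.where(tgt["has_town"], tgt["town"], ""),
            "dept_code": np.where(tgt["has_town"], tgt["dept"], ""),
            "tumor_type": tgt["ttype"],
            "stay_start_date": _iso(tgt["stay"], np.ones(len(tgt), bool)),
            "facility_code": tgt["facility"],
            "resection_date": _iso(tgt["resection"], tgt["has_resection"]),
            "biopsy_date": _iso(tgt["biopsy"], tgt["has_biopsy"]),
            "chemo_date": _iso(tgt["chemo"], tgt["has_chemo"]),
            "radio_date": _iso(tgt["radio"], tgt["has_radio"]),
            "reexcision_date": _iso(tgt["reexcision"], tgt["has_reexcision"]),
            "icd10_code": tgt["icd"],
        },
        columns=TARGET_COLUMNS,
    )

    # ---- source-side missingness -------------------------------------------
    def mask_for(variable: str) -> np.ndarray:
        per = cfg.missingness.get(variable)
        if not per:
            return np.zeros(ns, dtype=bool)
        p = np.array([per.get(s, 0.0) for s in subset])
        return rng.random(ns) < p

    m_town = mask_for("town_code")
    # department missingness is nested inside town missingness (coarse can
    # only be missing when the fine level already is); marginal rates are
    # preserved by conditioning on the town mask
    p_dept = np.array([cfg.missingness.get("dept_code", {}).get(s, 0.0) for s in subset])
    p_town = np.array([max(cfg.missingness.get("town_code", {}).get(s, 1e-12), 1e-12) for s in subset])
    m_dept = m_town & (rng.random(ns) < np.minimum(1.0, p_dept / p_town))
    m_surgery = mask_for("surgery_date")
    m_facility = mask_for("facility_code")
    m_type = mask_for("tumor_type")
    m_res = mask_for("resection_date")
    m_bio = mask_for("biopsy_date")
    m_death = mask_for("death_date")

    for var, m, applicable in [
        ("town_code", m_town, np.ones(ns, bool)),
        ("dept_code", m_dept, np.ones(ns, bool)),
        ("surgery_date", m_surgery, np.ones(ns, bool)),
        ("facility_code", m_facility, np.ones(ns, bool)),
        ("tumor_type", m_type, np.ones(ns, bool)),
        ("resection_date", m_res, has_resection),
        ("biopsy_date", m_bio, has_biopsy),
        ("death_date", m_death, dead),
    ]:
        for i in np.flatnonzero(m & applicable):
            log_rows.append(dict(side="source", idx=int(i), variable=var,
                                 action="masked", detail=""))

    source_df = pd.DataFrame(
        {
            "patient_id": source_ids,
            "subset": subset,
            "sex": sex,
            "birth_date": _iso(birth, np.ones(ns, bool)),
            "death_date": _iso(death, dead & ~m_death),
            "town_code": np.where(m_town, "", town),
            "dept_code": np.where(m_dept, "", dept),
            "tumor_type": np.where(m_type, "", ttype),
            "tumor_site": site,
            "surgery_date": _iso(surgery, ~m_surgery),
            "facility_code": np.where(m_facility, "", facility),
            "resection_date": _iso(resection, has_resection & ~m_res),
            "biopsy_date": _iso(biopsy, has_biopsy & ~m_bio),
            "chemo_indication_date": _iso(ind_date["chemo"], has_ind["chemo"]),
            "radio_indication_date": _iso(ind_date["radio"], has_ind["radio"]),
            "reexcision_indication_date": _iso(ind_date["reexcision"], has_ind["reexcision"]),
        },
        columns=SOURCE_COLUMNS,
    )

    log_df = pd.DataFrame(
        [
            {
                "side": r["side"],
                "record_id": r.get("rid")
                or (source_ids[r["idx"]] if r["side"] == "source" else idx_to_tid[r["idx"]]),
                "variable": r["variable"],
                "action": r["action"],
                "detail": str(r["detail"]),
            }
            for r in log_rows
        ],
        columns=["side", "record_id", "variable", "action", "detail"],
    )
    return source_df, target_df, truth, log_df


def generate(cfg: SimulationConfig):
    """Generate and normalize: (source RecordSet, target RecordSet, TruthMap)."""
    source_df, target_df, truth_df, log_df = generate_frames(cfg)
    book = default_book()
    source = load_records(source_df, book, "source")
    target = load_records(target_df, book, "target")
    truth = TruthMap(
        mapping=dict(zip(truth_df["source_id"], truth_df["target_id"])),
        corruption_log=log_df,
    )
    truth.validate(cfg.n_source)
    return source, target, truth


def scenario_table(cfg_grid: dict[str, list]) -> pd.DataFrame:
    """Cross-product of parameter lists with stable scenario ids."""
    keys = sorted(cfg_grid)
    rows: list[dict] = []

    def rec(i: int, current: dict):
        if i == len(keys):
            sid = hashlib.sha1(repr(sorted(current.items())).encode()).hexdigest()[:10]
            rows.append({"scenario_id": sid, **current})
            return
        for v in cfg_grid[keys[i]]:
            rec(i + 1, {**current, keys[i]: v})

    if keys:
        rec(0, {})
    return pd.DataFrame(rows, columns=["scenario_id", *keys])
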