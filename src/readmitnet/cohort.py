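"""Cohort construction: eligibility, index stays, readmissions, contacts.

Turns an event-level :class:`~readmitnet.data.ClaimsDataset` into one
analyzable record per patient: the set of index diagnoses (d1 candidates,
main + secondary codes of the first stay), the readmission outcome with its
main diagnosis (d2), and binary per-specialty contact flags (s), plus the
list of diagnosis combinations D=(d1, d2) frequent enough to analyze.

All thresholds live in :class:`CohortConfig`; the robustness variants
(shorter readmission window, lower case threshold, no age floor) are pure
config changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from datetime import date, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

from .data import ClaimsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "select_study_base",
    "extract_index",
    "eligible_index_codes",
    "detect_readmission",
    "ascertain_contacts",
    "enumerate_combinations",
    "build_cohort",
    "cohort_long",
]

CONTACT_PREFIX = "contact::"


@dataclass
class CohortConfig:
    """Eligibility and ascertainment rules.

    ``min_age`` is strict (a patient aged exactly ``min_age`` at observation
    start is excluded); ``max_age`` (strict ``<``) is only set by the
    no-age-floor robustness variant.  The readmission window endpoints are
    inclusive on both sides; controls are followed for ``follow_up_days``
    after the index date (inclusive), the same horizon as the readmission
    window's high end so cases and controls share one horizon.
    """

    min_age: float | None = 50.0
    max_age: float | None = None
    index_window: tuple[date, date] | None = None  # None: first 3 calendar years
    readmission_window_days: tuple[int, int] = (90, 1050)
    follow_up_days: int = 1050
    code_range: tuple[str, str] = ("A01", "N99")
    excluded_codes: tuple[str, ...] = ()
    min_index_dx_count: int = 1000
    min_combination_cases: int = 50
    specialty_list: tuple[str, ...] | None = None  # None: every contact code seen

    def validate(self) -> None:
        lo, hi = self.readmission_window_days
        if lo < 0 or lo >= hi:
            raise ValueError("readmission_window_days must satisfy 0 <= low < high")
        if self.min_index_dx_count < 1 or self.min_combination_cases < 1:
            raise ValueError("minimum counts must be >= 1")
        if self.index_window is not None and self.index_window[0] > self.index_window[1]:
            raise ValueError("index_window start must not exceed its end")

    def resolve_index_window(self, dataset: ClaimsDataset) -> tuple[date, date]:
        if self.index_window is not None:
            return self.index_window
        start = dataset.observation_start
        end = date(start.year + 3, 1, 1) - timedelta(days=1)
        return start, min(end, dataset.observation_end)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["index_window"] is not None:
            d["index_window"] = [x.isoformat() for x in d["index_window"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if d.get("index_window"):
            d["index_window"] = tuple(date.fromisoformat(x) for x in d["index_window"])
        for key in ("readmission_window_days", "code_range", "excluded_codes", "specialty_list"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _admissions(dataset: ClaimsDataset) -> pd.DataFrame:
    adm = dataset.events[dataset.events["event_type"] == "admission"].copy()
    adm["event_date"] = pd.to_datetime(adm["event_date"])
    return adm


def select_study_base(dataset: ClaimsDataset, cfg: CohortConfig) -> set:
    """Patients with known age and sex, inside the age bounds, and with at
    least one admission in the index window.

    The age criterion is strict on both ends: older than ``min_age`` and (if
    set) younger than ``max_age`` at observation start.
    """
    ev = dataset.events
    if len(ev) == 0:
        return set()
    info = ev.groupby("patient_id").agg(sex=("sex", "first"), age=("age_at_start", "first"))
    ok = info["sex"].isin(["m", "f"]) & info["age"].notna()
    if cfg.min_age is not None:
        ok &= info["age"] > cfg.min_age
    if cfg.max_age is not None:
        ok &= info["age"] < cfg.max_age

    win_lo, win_hi = cfg.resolve_index_window(dataset)
    adm = _admissions(dataset)
    in_win = adm[
        (adm["event_date"] >= pd.Timestamp(win_lo)) & (adm["event_date"] <= pd.Timestamp(win_hi))
    ]
    has_adm = set(in_win["patient_id"].unique())
    base = set(info.index[ok]) & has_adm
    logger.info(
        "study base: %d of %d patients (age window %s-%s, index window %s..%s)",
        len(base), len(info), cfg.min_age, cfg.max_age, win_lo, win_hi,
    )
    return base


def _in_code_range(codes: pd.Series, cfg: CohortConfig) -> pd.Series:
    lo, hi = cfg.code_range
    ok = (codes >= lo) & (codes <= hi)
    if cfg.excluded_codes:
        ok &= ~codes.isin(cfg.excluded_codes)
    return ok


def extract_index(
    dataset: ClaimsDataset, study_base: set, cfg: CohortConfig
) -> pd.DataFrame:
    """One skeleton record per patient: earliest admission in the index
    window becomes the index stay; its admissible codes become ``index_dx``.

    Multiple admission rows on the index date are merged into one stay whose
    diagnosis set is the union of their codes.  Patients whose code set is
    empty after the range/exclusion filter are dropped.
    """
    win_lo, win_hi = cfg.resolve_index_window(dataset)
    adm = _admissions(dataset)
    adm = adm[adm["patient_id"].isin(study_base)]
    adm = adm[
        (adm["event_date"] >= pd.Timestamp(win_lo)) & (adm["event_date"] <= pd.Timestamp(win_hi))
    ]
    if len(adm) == 0:
        return pd.DataFrame(
            columns=["patient_id", "sex", "age", "index_date", "index_dx"]
        )
    first_date = adm.groupby("patient_id")["event_date"].min().rename("index_date")
    adm = adm.join(first_date, on="patient_id")
    stay = adm[adm["event_date"] == adm["index_date"]].copy()
    stay = stay[_in_code_range(stay["code"].astype(str), cfg)]
    grouped = (
        stay.groupby("patient_id")
        .agg(
            sex=("sex", "first"),
            age=("age_at_start", "first"),
            index_date=("index_date", "first"),
            index_dx=("code", lambda c: frozenset(c)),
        )
        .reset_index()
    )
    n_dropped = len(study_base) - len(grouped)
    if n_dropped:
        logger.info("extract_index: dropped %d patients with no admissible index code", n_dropped)
    return grouped


def eligible_index_codes(records: pd.DataFrame, cfg: CohortConfig) -> set[str]:
    """Index codes occurring at least ``min_index_dx_count`` times across the
    patients' index diagnosis sets (each patient counts a code once)."""
    if len(records) == 0:
        return set()
    counts = pd.Series(
        [c for dx in records["index_dx"] for c in dx], dtype=object
    ).value_counts()
    return set(counts.index[counts >= cfg.min_index_dx_count])


def detect_readmission(
    records: pd.DataFrame, dataset: ClaimsDataset, cfg: CohortConfig
) -> pd.DataFrame:
    """Fill the readmission outcome.

    A patient is readmitted iff some admission falls ``low <= delta <= high``
    days after the index date (both endpoints inclusive); the earliest such
    admission supplies the readmission date and its main diagnosis (d2).
    Records whose qualifying stay lacks a main diagnosis are dropped with a
    logged warning.
    """
    out = records.copy()
    out["readmitted"] = False
    out["readmission_date"] = pd.NaT
    out["readmission_main_dx"] = pd.NA
    if len(out) == 0:
        return out

    lo, hi = cfg.readmission_window_days
    adm = _admissions(dataset)
    adm = adm[adm["patient_id"].isin(set(out["patient_id"]))]
    adm = adm.merge(out[["patient_id", "index_date"]], on="patient_id")
    delta = (adm["event_date"] - adm["index_date"]).dt.days
    qual = adm[(delta >= lo) & (delta <= hi)]
    if len(qual):
        first = qual.groupby("patient_id")["event_date"].min().rename("readmission_date")
        qual = qual.join(first, on="patient_id")
        at_first = qual[qual["event_date"] == qual["readmission_date"]]
        main = at_first[at_first["dx_role"] == "main"]
        main_dx = main.groupby("patient_id")["code"].first()
        readmit_date = first

        out = out.set_index("patient_id")
        readmitted_ids = readmit_date.index
        out.loc[readmitted_ids, "readmitted"] = True
        out.loc[readmitted_ids, "readmission_date"] = readmit_date
        out.loc[main_dx.index, "readmission_main_dx"] = main_dx
        no_main = out.index[out["readmitted"] & out["readmission_main_dx"].isna()]
        if len(no_main):
            logger.warning(
                "detect_readmission: dropping %d records whose qualifying "
                "readmission lacks a main diagnosis", len(no_main),
            )
            out = out.drop(index=no_main)
        out = out.reset_index()
    return out


def ascertain_contacts(
    records: pd.DataFrame, dataset: ClaimsDataset, cfg: CohortConfig
) -> pd.DataFrame:
    """Fill one boolean column per specialty (``contact::<s>``).

    A flag is true iff at least one contact with that specialty occurred
    strictly after the index date and — for readmitted patients — strictly
    before the readmission date, or — for controls — within
    ``follow_up_days`` of the index date (inclusive).  Contact events whose
    specialty is not in the configured list are ignored and tallied in a log
    summary.
    """
    out = records.copy()
    contacts = dataset.events[dataset.events["event_type"] == "contact"].copy()
    contacts["event_date"] = pd.to_datetime(contacts["event_date"])
    if cfg.specialty_list is not None:
        specialties = list(cfg.specialty_list)
        unknown = contacts[~contacts["code"].isin(specialties)]
        if len(unknown):
            logger.info(
                "ascertain_contacts: ignoring %d contacts with specialties "
                "outside the configured list: %s",
                len(unknown), sorted(unknown["code"].unique()),
            )
        contacts = contacts[contacts["code"].isin(specialties)]
    else:
        specialties = sorted(contacts["code"].unique())

    for s in specialties:
        out[CONTACT_PREFIX + s] = False
    if len(out) == 0 or len(contacts) == 0:
        return out

    merged = contacts.merge(
        out[["patient_id", "index_date", "readmitted", "readmission_date"]],
        on="patient_id",
    )
    delta = (merged["event_date"] - merged["index_date"]).dt.days
    after_index = delta > 0
    case_ok = merged["readmitted"] & (merged["event_date"] < merged["readmission_date"])
    ctrl_ok = ~merged["readmitted"] & (delta <= cfg.follow_up_days)
    hits = merged[after_index & (case_ok | ctrl_ok)]
    flags = hits.groupby(["patient_id", "code"]).size().unstack(fill_value=0) > 0

    out = out.set_index("patient_id")
    for s in specialties:
        if s in flags.columns:
            idx = flags.index[flags[s]]
            out.loc[idx.intersection(out.index), CONTACT_PREFIX + s] = True
    return out.reset_index()


def contact_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith(CONTACT_PREFIX)]


def specialties_of(records: pd.DataFrame) -> list[str]:
    return [c[len(CONTACT_PREFIX):] for c in contact_columns(records)]


def enumerate_combinations(
    records: pd.DataFrame,
    cfg: CohortConfig,
    eligible_codes: Iterable[str] | None = None,
    by_sex: bool = True,
) -> pd.DataFrame:
    """Diagnosis combinations D=(d1, d2) with at least the configured number
    of cases.

    ``n_cases`` counts readmitted patients with ``d1`` among their index
    diagnoses and ``d2`` as readmission main diagnosis; a patient with k
    eligible index codes contributes to k combinations.  The case threshold
    is applied within sex strata when ``by_sex`` (each stratum is modelled
    separately downstream).
    """
    cols = ["d1", "d2", "sex", "n_cases"] if by_sex else ["d1", "d2", "n_cases"]
    re_rec = records[records["readmitted"]]
    if len(re_rec) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for rec in re_rec.itertuples(index=False):
        for d1 in rec.index_dx:
            if eligible_codes is not None and d1 not in eligible_codes:
                continue
            rows.append((d1, rec.readmission_main_dx, rec.sex))
    if not rows:
        return pd.DataFrame(columns=cols)
    long = pd.DataFrame(rows, columns=["d1", "d2", "sex"])
    keys = ["d1", "d2", "sex"] if by_sex else ["d1", "d2"]
    counts = long.groupby(keys).size().rename("n_cases").reset_index()
    counts = counts[counts["n_cases"] >= cfg.min_combination_cases]
    return counts.sort_values(keys, kind="mergesort").reset_index(drop=True)[cols]


def build_cohort(
    dataset: ClaimsDataset, cfg: CohortConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Run the full cohort stage.

    Returns ``(records, combinations, eligible_codes)`` where ``records`` has
    one row per analyzable patient with outcome and contact flags filled.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    base = select_study_base(dataset, cfg)
    records = extract_index(dataset, base, cfg)
    records = detect_readmission(records, dataset, cfg)
    records = ascertain_contacts(records, dataset, cfg)
    codes = eligible_index_codes(records, cfg)
    combos = enumerate_combinations(records, cfg, eligible_codes=codes)
    logger.info(
        "cohort: %d records, %d eligible index codes, %d combinations",
        len(records), len(codes), len(combos),
    )
    return records, combos, codes


def cohort_long(records: pd.DataFrame, eligible_codes: Iterable[str] | None = None) -> pd.DataFrame:
    """Flat export: one row per patient x (eligible) index code."""
    rows = []
    eligible = set(eligible_codes) if eligible_codes is not None else None
    flag_cols = contact_columns(records)
    for rec_d in records.to_dict("records"):
        for d1 in sorted(rec_d["index_dx"]):
            if eligible is not None and d1 not in eligible:
                continue
            row = {
                "patient_id": rec_d["patient_id"],
                "sex": rec_d["sex"],
                "age": rec_d["age"],
                "index_date": rec_d["index_date"],
                "d1": d1,
                "readmitted": rec_d["readmitted"],
                "readmission_main_dx": rec_d["readmission_main_dx"],
            }
            for c in flag_cols:
                row[c] = rec_d[c]
            rows.append(row)
    return pd.DataFrame(rows)
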