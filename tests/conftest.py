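"""Shared fixtures: hand-built event tables and small simulated worlds."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from readmitnet.cohort import CONTACT_PREFIX, CohortConfig
from readmitnet.data import ClaimsDataset
from readmitnet.simulate import SimulationConfig, generate_dataset

START = date(2006, 1, 1)
END = date(2012, 3, 31)


def make_dataset(patients, start=START, end=END) -> ClaimsDataset:
    """Build a ClaimsDataset from a compact per-patient description.

    ``patients`` is a list of dicts with keys ``id, sex, age, events`` where
    each event is ``(day_offset, "admission", code, role)`` or
    ``(day_offset, "contact", specialty)``.
    """
    rows = []
    for p in patients:
        for ev in p["events"]:
            if ev[1] == "admission":
                day, _, code, role = ev
            else:
                day, _, code = ev
                role = "n/a"
            rows.append(
                {
                    "patient_id": p["id"],
                    "sex": p["sex"],
                    "age_at_start": p["age"],
                    "event_type": ev[1],
                    "event_date": pd.Timestamp(start) + pd.Timedelta(days=day),
                    "code": code,
                    "dx_role": role,
                }
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sex", "age_at_start", "event_type", "event_date", "code", "dx_role",
        ],
    )
    return ClaimsDataset(events, start, end)


def make_records(rows, specialties=("internal medicine",)) -> pd.DataFrame:
    """Build a cohort-record table directly (bypassing event extraction).

    Each row dict may carry ``patient_id, sex, age, index_dx (iterable),
    readmitted, readmission_main_dx`` and per-specialty contact booleans
    under the specialty name.
    """
    out = []
    for i, r in enumerate(rows):
        rec = {
            "patient_id": r.get("patient_id", i),
            "sex": r.get("sex", "m"),
            "age": r.get("age", 70.0),
            "index_date": pd.Timestamp(START) + pd.Timedelta(days=r.get("index_day", 10)),
            "index_dx": frozenset(r.get("index_dx", {"I25"})),
            "readmitted": r.get("readmitted", False),
            "readmission_main_dx": r.get("readmission_main_dx", pd.NA),
            "readmission_date": (
                pd.Timestamp(START) + pd.Timedelta(days=r["readmission_day"])
                if "readmission_day" in r
                else pd.NaT
            ),
        }
        for s in specialties:
            rec[CONTACT_PREFIX + s] = bool(r.get(s, False))
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_world():
    """A moderately sized simulated world with protective contact effects,
    plus a cohort configuration with thresholds scaled to its size."""
    sim = SimulationConfig(n_patients=6000, seed=11)
    cohort_cfg = CohortConfig(min_index_dx_count=200, min_combination_cases=30)
    return sim, generate_dataset(sim), cohort_cfg
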