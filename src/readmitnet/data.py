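"""Event-level claims container.

A :class:`ClaimsDataset` holds one row per event: hospital admissions carrying
a 3-digit ICD-10 code (with a main/secondary role) and specialist contacts
carrying a specialty label.  Each patient has exactly one sex and one age at
the start of the observation window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

ICD10_3DIGIT = re.compile(r"^[A-Z][0-9]{2}$")

EVENT_COLUMNS = [
    "patient_id",
    "sex",
    "age_at_start",
    "event_type",
    "event_date",
    "code",
    "dx_role",
]

SEXES = ("m", "f")
EVENT_TYPES = ("admission", "contact")
DX_ROLES = ("main", "secondary", "n/a")


class SchemaError(ValueError):
    """An event table does not conform to the claims schema."""


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()


@dataclass
class ClaimsDataset:
    """Longitudinal claims events plus the observation window they cover.

    Parameters
    ----------
    events
        Table with columns ``patient_id, sex, age_at_start, event_type,
        event_date, code, dx_role``.  ``event_date`` is datetime-like.
    observation_start, observation_end
        Calendar bounds of the observation window; every event date must fall
        inside them.  Ages are taken at ``observation_start``.
    """

    events: pd.DataFrame
    observation_start: date
    observation_end: date

    def __post_init__(self) -> None:
        self.observation_start = _as_date(self.observation_start)
        self.observation_end = _as_date(self.observation_end)

    @property
    def n_patients(self) -> int:
        return self.events["patient_id"].nunique()

    def validate(self) -> None:
        """Raise :class:`SchemaError` on any schema or invariant violation."""
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise SchemaError(f"event table is missing columns: {missing}")
        ev = self.events
        if len(ev) == 0:
            return
        bad_type = set(ev["event_type"].unique()) - set(EVENT_TYPES)
        if bad_type:
            raise SchemaError(f"unknown event types: {sorted(bad_type)}")
        bad_sex = set(ev["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")
        per_patient = ev.groupby("patient_id")[["sex", "age_at_start"]].nunique()
        multi = per_patient[(per_patient > 1).any(axis=1)]
        if len(multi):
            raise SchemaError(
                f"{len(multi)} patients have inconsistent sex or age_at_start"
            )
        dates = pd.to_datetime(ev["event_date"])
        lo, hi = pd.Timestamp(self.observation_start), pd.Timestamp(self.observation_end)
        if (dates < lo).any() or (dates > hi).any():
            raise SchemaError("event dates fall outside the observation window")
        adm = ev.loc[ev["event_type"] == "admission", "code"]
        bad_code = adm[~adm.astype(str).str.match(ICD10_3DIGIT)]
        if len(bad_code):
            raise SchemaError(
                f"{len(bad_code)} admission codes are not 3-digit ICD-10 "
                f"(e.g. {bad_code.iloc[0]!r})"
            )

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> None:
        """Write the event table as delimited text with ISO-8601 dates."""
        out = self.events.copy()
        out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    def to_parquet(self, path: str | Path) -> None:
        self.events.to_parquet(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        observation_start: date | str | None = None,
        observation_end: date | str | None = None,
    ) -> "ClaimsDataset":
        """Read an event table; infer the observation window from the data
        when bounds are not given."""
        ev = pd.read_csv(path, dtype={"code": str, "sex": str, "dx_role": str})
        ev["event_date"] = pd.to_datetime(ev["event_date"])
        if observation_start is None:
            observation_start = ev["event_date"].min().date() if len(ev) else date(1970, 1, 1)
        if observation_end is None:
            observation_end = ev["event_date"].max().date() if len(ev) else date(1970, 1, 1)
        return cls(ev, _as_date(observation_start), _as_date(observation_end))


def empty_events() -> pd.DataFrame:
    """An empty event table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype="int64"),
            "sex": pd.Series(dtype="object"),
            "age_at_start": pd.Series(dtype="float64"),
            "event_type": pd.Series(dtype="object"),
            "event_date": pd.Series(dtype="datetime64[ns]"),
            "code": pd.Series(dtype="object"),
            "dx_role": pd.Series(dtype="object"),
        }
    )
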