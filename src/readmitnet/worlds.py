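"""Canonical synthetic validation worlds.

Three generator setups with known ground truth, used to validate the
pipeline end to end:

* :func:`single_cell_world` — one diagnosis, one specialty, a configurable
  contact effect: the sharpest possible parameter-recovery target, since the
  fitted model coincides with the generating model.
* :func:`null_world` — several diagnoses and specialties with all contact
  effects zero: contact is independent of readmission, so any significant
  finding downstream is a false positive (calibration check).
* :func:`protective_world` — the same layout with a uniformly protective
  contact effect: every true relative risk is below one (directionality
  check).
"""

from __future__ import annotations

import math

from .cohort import CohortConfig
from .simulate import SimulationConfig, uniform_table

__all__ = ["single_cell_world", "null_world", "protective_world"]

_FIVE_DIAGNOSES = ("E11", "E78", "I21", "I25", "J44")
_TWO_SPECIALTIES = ("internal medicine", "radiology")


def _self_heavy_d2(codes, self_weight=0.5):
    """Readmission diagnosis distribution: half the mass on the index
    diagnosis itself, the rest spread evenly (chronic disease tends to drive
    its own readmissions)."""
    out = {}
    for d1 in codes:
        others = [c for c in codes if c != d1]
        out[d1] = {d1: self_weight, **{c: (1 - self_weight) / len(others) for c in others}}
    return out


def single_cell_world(
    n_patients: int = 50_000, gamma: float = math.log(0.5), seed: int = 0
) -> tuple[SimulationConfig, CohortConfig]:
    """One diagnosis (I25), one specialty, contact effect ``gamma``."""
    sim = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        diagnosis_catalog={"I25": 1.0},
        specialty_catalog=["internal medicine"],
        readmission_intercept={"m": {"I25": -1.75}, "f": {"I25": -1.85}},
        age_slope=0.02,
        contact_effect={"I25": {"internal medicine": gamma}},
        contact_prob_intercept={"m": {"internal medicine": -0.7}, "f": {"internal medicine": -0.7}},
        contact_age_slope=0.01,
        readmission_dx_distribution={"I25": {"I25": 1.0}},
    )
    cohort = CohortConfig()  # paper-scale thresholds are attainable at this n
    return sim, cohort


def _multi_world(n_patients: int, gamma: float, seed: int):
    codes = list(_FIVE_DIAGNOSES)
    specialties = list(_TWO_SPECIALTIES)
    sim = SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        diagnosis_catalog={c: 1.0 / len(codes) for c in codes},
        specialty_catalog=specialties,
        readmission_intercept={
            "m": {c: -1.70 for c in codes},
            "f": {c: -1.78 for c in codes},
        },
        age_slope=0.02,
        contact_effect=uniform_table(codes, specialties, gamma),
        contact_prob_intercept={
            sx: {"internal medicine": -0.4, "radiology": -0.2} for sx in ("m", "f")
        },
        contact_age_slope=0.01,
        readmission_dx_distribution=_self_heavy_d2(codes),
    )
    return sim, CohortConfig()


def null_world(n_patients: int = 20_000, seed: int = 0):
    """Five diagnoses, two specialties, every contact effect zero."""
    return _multi_world(n_patients, 0.0, seed)


def protective_world(
    n_patients: int = 20_000, gamma: float = math.log(0.5), seed: int = 0
):
    """Same layout with a uniformly protective contact effect (gamma < 0)."""
    if gamma >= 0:
        raise ValueError("protective world requires gamma < 0")
    return _multi_world(n_patients, gamma, seed)
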