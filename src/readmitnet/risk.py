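"""Age-adjusted logistic risk models.

Three model families, all stratified by sex and evaluated at the mean
population age:

* ``P_diag(sex, d1)`` — probability of any readmission for carriers of index
  diagnosis d1, from a logistic fit of readmitted ~ age;
* ``P_spec(sex, s)`` — probability of at least one contact with specialty s,
  from contact ~ age;
* ``Q(sex, D, s)`` — probability of readmission with main diagnosis d2 given
  index diagnosis d1, from a fit with covariates age and a binary contact
  dummy, evaluated with the dummy set to 1 (q1) and 0 (q0).  The relative
  readmission risk of the cell is RR = q1 / q0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .cohort import CONTACT_PREFIX

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateOutcomeError",
    "FitError",
    "CellSkipped",
    "RiskEstimate",
    "RelativeRisk",
    "fit_logistic",
    "diagnosis_readmission_risk",
    "specialist_contact_probability",
    "contact_dependent_risk",
    "mean_age",
]


class DegenerateOutcomeError(ValueError):
    """All outcomes are positive or all are negative; no logistic fit exists."""


class FitError(RuntimeError):
    """The design matrix is rank deficient or the fit failed outright."""


class CellSkipped(RuntimeError):
    """A (D, s) cell cannot be estimated (zero cell in contact x outcome)."""


@dataclass
class RiskEstimate:
    """An age-adjusted probability with its fit metadata.

    ``coefficients`` are on the log-odds scale in the order
    (intercept, age slope[, contact effect]); ``se`` is the delta-method
    standard error of the probability.
    """

    sex: str
    target: object
    probability: float
    eval_age: float
    coefficients: np.ndarray
    n_obs: int
    converged: bool
    se: float | None = None


@dataclass
class RelativeRisk:
    """Relative readmission risk for one (sex, D=(d1,d2), s) cell."""

    sex: str
    d1: str
    d2: str
    s: str
    q1: float
    q0: float
    rr: float
    n1: int
    n0: int
    converged: bool
    eval_age: float


def fit_logistic(outcome: np.ndarray, covariates: np.ndarray | None):
    """Maximum-likelihood logistic fit with an intercept.

    Parameters
    ----------
    outcome
        Binary response vector.
    covariates
        Numeric matrix (n, p), or ``None``/empty for an intercept-only model.

    Returns
    -------
    (params, cov, converged)
        Coefficient vector (intercept first), covariance matrix, and a
        convergence flag.  Separation or non-convergence is reported through
        the flag (with NaN parameters for hard failures), never silently.
    """
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("outcome must be a nonempty 1-d binary vector")
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            f"outcome is constant ({y[0]:g}); logistic MLE does not exist"
        )
    if covariates is None:
        X = np.ones((len(y), 1))
    else:
        Xc = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Xc.shape[0] != len(y):
            Xc = Xc.T
        if not np.all(np.isfinite(Xc)):
            raise ValueError("covariates must be finite")
        X = np.column_stack([np.ones(len(y)), Xc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False)) and not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        return np.asarray(res.params), np.asarray(res.cov_params()), converged
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        logger.warning("fit_logistic: %s", exc)
        k = X.shape[1]
        return np.full(k, np.nan), np.full((k, k), np.nan), False


def _prob_at(params: np.ndarray, cov: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Probability at covariate vector ``x`` plus its delta-method SE."""
    p = float(expit(x @ params))
    var_eta = float(x @ cov @ x)
    se = p * (1.0 - p) * np.sqrt(max(var_eta, 0.0))
    return p, se


def mean_age(records: pd.DataFrame, sex: str | None = None) -> float:
    """Mean age of the study base, optionally within one sex stratum."""
    sub = records if sex is None else records[records["sex"] == sex]
    return float(sub["age"].mean())


def _age_risk(
    records: pd.DataFrame,
    outcome: np.ndarray,
    sex: str,
    target,
    eval_age: float,
    ages: np.ndarray,
    age_adjusted: bool,
) -> RiskEstimate:
    X = ages.reshape(-1, 1) if age_adjusted else None
    params, cov, converged = fit_logistic(outcome, X)
    x = np.array([1.0, eval_age]) if age_adjusted else np.array([1.0])
    p, se = _prob_at(params, cov, x)
    return RiskEstimate(
        sex=sex,
        target=target,
        probability=p,
        eval_age=eval_age,
        coefficients=params,
        n_obs=len(outcome),
        converged=converged,
        se=se,
    )


def diagnosis_readmission_risk(
    records: pd.DataFrame,
    d1: str,
    sex: str,
    eval_age: float | None = None,
    age_adjusted: bool = True,
) -> RiskEstimate:
    """Age-adjusted readmission risk P_diag for carriers of ``d1``.

    Fits readmitted ~ age on the records of that sex with ``d1`` among the
    index diagnoses and evaluates the model at ``eval_age`` (defaults to the
    stratum's mean age).
    """
    sub = records[(records["sex"] == sex) & records["index_dx"].map(lambda dx: d1 in dx)]
    if len(sub) == 0:
        raise ValueError(f"no records of sex {sex!r} carrying {d1!r}")
    if eval_age is None:
        eval_age = float(sub["age"].mean())
    return _age_risk(
        sub,
        sub["readmitted"].to_numpy(dtype=float),
        sex,
        d1,
        eval_age,
        sub["age"].to_numpy(dtype=float),
        age_adjusted,
    )


def specialist_contact_probability(
    records: pd.DataFrame,
    s: str,
    sex: str,
    eval_age: float | None = None,
    age_adjusted: bool = True,
) -> RiskEstimate:
    """Age-adjusted probability P_spec of at least one contact with ``s``."""
    col = CONTACT_PREFIX + s
    if col not in records.columns:
        raise KeyError(f"no contact flags for specialty {s!r}")
    sub = records[records["sex"] == sex]
    if len(sub) == 0:
        raise ValueError(f"no records of sex {sex!r}")
    if eval_age is None:
        eval_age = float(sub["age"].mean())
    return _age_risk(
        sub,
        sub[col].to_numpy(dtype=float),
        sex,
        s,
        eval_age,
        sub["age"].to_numpy(dtype=float),
        age_adjusted,
    )


def contact_dependent_risk(
    records: pd.DataFrame,
    d1: str,
    d2: str,
    s: str,
    sex: str,
    eval_age: float | None = None,
    age_adjusted: bool = True,
    condition_on_readmitted: bool = False,
) -> RelativeRisk:
    """Contact-dependent readmission risk Q and the cell's relative risk.

    The record universe is every patient of the given sex with ``d1`` among
    the index diagnoses.  The outcome is "readmitted with main diagnosis
    ``d2``"; patients readmitted with another diagnosis count as outcome 0
    (set ``condition_on_readmitted`` to restrict the universe to readmitted
    patients instead).  One logistic fit with covariates (age, contact dummy)
    yields q1 and q0 by evaluating at ``eval_age`` with the dummy set to 1
    and 0; ``rr = q1/q0``.

    Raises
    ------
    CellSkipped
        If any cell of the 2x2 contact x outcome table is empty, or the fit
        is degenerate.
    """
    col = CONTACT_PREFIX + s
    if col not in records.columns:
        raise KeyError(f"no contact flags for specialty {s!r}")
    sub = records[(records["sex"] == sex) & records["index_dx"].map(lambda dx: d1 in dx)]
    if condition_on_readmitted:
        sub = sub[sub["readmitted"]]
    if len(sub) == 0:
        raise CellSkipped(f"no records for sex={sex}, d1={d1}")
    outcome = (
        sub["readmitted"] & (sub["readmission_main_dx"] == d2)
    ).to_numpy(dtype=float)
    contact = sub[col].to_numpy(dtype=float)
    n1 = int(contact.sum())
    n0 = len(contact) - n1

    table = np.array(
        [
            [np.sum((contact == c) & (outcome == o)) for o in (0, 1)]
            for c in (0, 1)
        ]
    )
    if (table == 0).any():
        raise CellSkipped(
            f"zero cell in contact x outcome table for "
            f"(sex={sex}, d1={d1}, d2={d2}, s={s}): {table.tolist()}"
        )
    if eval_age is None:
        eval_age = float(sub["age"].mean())

    ages = sub["age"].to_numpy(dtype=float)
    X = np.column_stack([ages, contact]) if age_adjusted else contact.reshape(-1, 1)
    try:
        params, cov, converged = fit_logistic(outcome, X)
    except (DegenerateOutcomeError, FitError) as exc:
        raise CellSkipped(str(exc)) from exc
    if age_adjusted:
        x1 = np.array([1.0, eval_age, 1.0])
        x0 = np.array([1.0, eval_age, 0.0])
    else:
        x1 = np.array([1.0, 1.0])
        x0 = np.array([1.0, 0.0])
    q1, _ = _prob_at(params, cov, x1)
    q0, _ = _prob_at(params, cov, x0)
    return RelativeRisk(
        sex=sex,
        d1=d1,
        d2=d2,
        s=s,
        q1=q1,
        q0=q0,
        rr=q1 / q0,
        n1=n1,
        n0=n0,
        converged=converged,
        eval_age=eval_age,
    )
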