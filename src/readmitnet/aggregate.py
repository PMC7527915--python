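"""Aggregation of cell-level relative risks, significance testing, FDR.

Cell-level relative readmission risks RR(sex, D, s) are summarized as
medians: per index diagnosis (over readmission diagnoses d2 and contacts s)
and per specialty (over diagnosis combinations D).  Each aggregated key gets
one p-value from a paired comparison of the contact-dependent risks q1
versus q0 across its cells — a paired t test when a Kolmogorov-Smirnov check
does not reject normality of the paired differences, a sign test otherwise —
and the Benjamini-Hochberg procedure controls the false discovery rate
within each results family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .risk import RelativeRisk

__all__ = [
    "AggregatedRR",
    "test_paired",
    "bh_correct",
    "aggregate_diagnosis",
    "aggregate_specialty",
    "aggregate_all",
]


@dataclass
class AggregatedRR:
    """Median relative risk for one key (an index diagnosis or a specialty).

    ``se`` is the SD of the contributing cell RRs divided by sqrt(n_cells);
    it is absent when a single cell contributed.  ``significant`` is filled
    after FDR correction across the key's family.
    """

    sex: str
    key: str
    rr_median: float
    se: float | None
    n_cells: int
    p_value: float
    test_name: str
    significant: bool | None = None


def test_paired(
    q1_set: Sequence[float],
    q0_set: Sequence[float],
    normality_alpha: float = 0.05,
) -> tuple[float, str]:
    """Paired comparison of contact (q1) vs no-contact (q0) risks.

    The paired differences are checked for normality with a
    Kolmogorov-Smirnov test against a normal law with mean and SD estimated
    from the differences (a Lilliefors-style use of KS: estimating the
    parameters makes the nominal KS level conservative, which is accepted
    here).  If normality is not rejected at ``normality_alpha``, a paired
    t test is used; otherwise a two-sided sign test (zero differences
    dropped; all-zero differences give p = 1 by convention).
    """
    q1 = np.asarray(q1_set, dtype=float)
    q0 = np.asarray(q0_set, dtype=float)
    if q1.shape != q0.shape:
        raise ValueError("q1_set and q0_set must have equal length (paired by cell)")
    if len(q1) < 1:
        raise ValueError("need at least one pair")
    d = q1 - q0

    def _sign_test() -> tuple[float, str]:
        nonzero = d[d != 0]
        if len(nonzero) == 0:
            return 1.0, "sign"
        k = int((nonzero > 0).sum())
        p = stats.binomtest(k, len(nonzero), 0.5, alternative="two-sided").pvalue
        return float(min(p, 1.0)), "sign"

    sd = d.std(ddof=1) if len(d) > 1 else 0.0
    if len(d) < 2 or sd == 0.0:
        return _sign_test()
    ks_p = stats.kstest(d, "norm", args=(d.mean(), sd)).pvalue
    if ks_p >= normality_alpha:
        t_p = stats.ttest_rel(q1, q0).pvalue
        return float(t_p), "t"
    return _sign_test()


def bh_correct(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``alpha``.

    Sort ascending, find the largest k with p_(k) <= k * alpha / m, reject
    hypotheses 1..k.  Empty input gives empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def _aggregate(cells: list[RelativeRisk], sex: str, key: str) -> AggregatedRR:
    rrs = np.array([c.rr for c in cells], dtype=float)
    q1 = [c.q1 for c in cells]
    q0 = [c.q0 for c in cells]
    p, name = test_paired(q1, q0)
    se = float(rrs.std(ddof=1) / np.sqrt(len(rrs))) if len(rrs) > 1 else None
    return AggregatedRR(
        sex=sex,
        key=key,
        rr_median=float(np.median(rrs)),
        se=se,
        n_cells=len(rrs),
        p_value=p,
        test_name=name,
    )


def aggregate_diagnosis(cells: Iterable[RelativeRisk], d1: str, sex: str) -> AggregatedRR:
    """Diagnosis-specific relative readmission risk RR_diag(sex, d1):
    median of cell RRs over all (d2, s) combinations for that diagnosis."""
    sub = [c for c in cells if c.d1 == d1 and c.sex == sex]
    if not sub:
        raise ValueError(f"no cells for d1={d1!r}, sex={sex!r}")
    return _aggregate(sub, sex, d1)


def aggregate_specialty(cells: Iterable[RelativeRisk], s: str, sex: str) -> AggregatedRR:
    """Specialty-specific relative readmission risk RR_spec(sex, s):
    median of cell RRs over all diagnosis combinations D."""
    sub = [c for c in cells if c.s == s and c.sex == sex]
    if not sub:
        raise ValueError(f"no cells for s={s!r}, sex={sex!r}")
    return _aggregate(sub, sex, s)


def aggregate_all(
    cells: Sequence[RelativeRisk], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate all cells into the two result families and apply BH.

    Returns (diagnosis table, specialty table); FDR is controlled within
    each family separately per sex (family structure is a documented choice;
    the grouping is what varies, the procedure is identical).
    """

    def _family(group_attr: str, agg_fn) -> pd.DataFrame:
        results: list[AggregatedRR] = []
        for sex in ("m", "f"):
            keys = sorted({getattr(c, group_attr) for c in cells if c.sex == sex})
            fam = [agg_fn(cells, k, sex) for k in keys]
            if fam:
                flags = bh_correct([a.p_value for a in fam], alpha=alpha)
                for a, f in zip(fam, flags):
                    a.significant = bool(f)
            results.extend(fam)
        return pd.DataFrame(
            [
                {
                    "sex": a.sex,
                    "key": a.key,
                    "rr_median": a.rr_median,
                    "se": a.se,
                    "n_cells": a.n_cells,
                    "p_value": a.p_value,
                    "test": a.test_name,
                    "significant": a.significant,
                }
                for a in results
            ]
        )

    diag = _family("d1", aggregate_diagnosis)
    spec = _family("s", aggregate_specialty)
    return diag, spec
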