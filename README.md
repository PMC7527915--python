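# readmitnet

Sex-specific, age-adjusted **long-term hospital readmission risks** from
claims-style event tables, the effect of **specialist aftercare** on those
risks, and a filtered **patient-flow network** summarizing significant
diagnosis → specialty → diagnosis trajectories.

The package is aimed at health-services and network-medicine researchers
working with administrative claims data for elderly, multimorbid
populations. Because such data are almost always proprietary, the package
ships a seeded synthetic-claims generator with known ground-truth effects,
so every stage of the analysis is testable and its estimates can be checked
against closed-form truth.

## The model

From event-level claims (admissions with 3-digit ICD-10 codes, specialist
contacts), the pipeline builds one record per patient: the set of index
diagnoses *d₁* (main + secondary codes of the first hospital stay within the
index window, range A01–N99), the readmission outcome (earliest admission
90–1050 days after index; its main diagnosis is *d₂*), and a binary contact
flag per specialty *s* (at least one contact between index and readmission,
or within the 3-year follow-up for controls). Diagnosis combinations
*D* = (*d₁*, *d₂*) with at least 50 cases per sex stratum enter the analysis.

All models are sex-stratified logistic regressions evaluated at the mean
population age ā:

- **P_diag(m/f, d₁)** = σ(β̂₀ + β̂_age·ā) from `readmitted ~ age` on carriers
  of *d₁* — the age-adjusted readmission risk;
- **P_spec(m/f, s)** from `contact_s ~ age` — the age-adjusted contact
  probability;
- **Q(m/f, D, s)** from `readmitted_with_d₂ ~ age + contact_s`, evaluated
  with the contact dummy on (q₁) and off (q₀). The cell's **relative
  readmission risk** is RR = q₁/q₀; RR < 1 means lower readmission risk
  after specialist contact.

Cell RRs are aggregated as medians — per diagnosis (over *d₂* and *s*,
**RR_diag**) and per specialty (over *D*, **RR_spec**) — with one p-value
per key from a paired comparison of {q₁} vs {q₀} (paired *t* test when a
Kolmogorov–Smirnov check does not reject normality of the differences, sign
test otherwise) and Benjamini–Hochberg FDR control within each family.
Readmitted patients' trajectories form a directed tripartite network
*d₁* → *s* → *d₂* weighted by patient counts with a men/women ratio per
link; its backbone overlaps the maximum spanning tree with the disparity
filter (edge significance (1 − p)^(k−1) at a degree-*k* endpoint).

## Worked example

```python
import math
from readmitnet import RunConfig, run_pipeline, recovery_report
from readmitnet.worlds import protective_world

# 20,000 synthetic patients; every specialist contact halves the
# readmission odds (gamma = ln 0.5).
sim, cohort = protective_world(n_patients=20_000, gamma=math.log(0.5), seed=3)
result = run_pipeline(RunConfig(sim=sim, cohort=cohort))
print(result.agg_diagnosis.head(3).round(4))
table, summary = recovery_report(sim, result)
print(summary)
```

prints (abridged):

```
sex key  rr_median     se  n_cells  p_value test  significant
  m E11     0.6164 0.0247       10   0.0000    t         True
  m E78     0.6075 0.0202       10   0.0000    t         True
  m I21     0.5910 0.0266       10   0.0000    t         True
{'n_cells': 100, 'bias': -0.0147, 'rmse': 0.0903, ...}
```

An odds ratio of 0.5 at these baseline risks corresponds to a true risk
ratio near 0.61 at mean age; the medians recover it, every significant
aggregated RR is below 1, and the per-cell RMSE against the closed-form
ground truth is ≈0.09 at ~1,000 readmitted patients per cell universe.

The `examples/` directory walks through each capability (generation, cohort
rules, marginal risks, relative risks, network backbone, robustness
variants); each script prints its numbers with a note on what they mean.
A thin CLI mirrors the pipeline: `readmitnet simulate|cohort|fit|aggregate|
network|run|recover` (see `readmitnet run --help`).

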