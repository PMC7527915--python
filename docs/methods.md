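# Methods

## Study design emulated

The pipeline reproduces a retrospective claims-data cohort design for
elderly patients: every person older than 50 at the start of the
observation window with at least one hospital admission in the index window
(the first three calendar years) enters the study base. The earliest
admission is the *index hospitalization*; its main and secondary 3-digit
ICD-10 codes within A01–N99 are the candidate index diagnoses *d₁* (codes
outside that range — examinations, births, congenital malformations,
unspecific symptoms — are disregarded, and a patient with no admissible code
is dropped). A *readmission* is the earliest admission 90–1050 days after
the index date, both endpoints inclusive; its main diagnosis is *d₂*.
Specialist contact is binary: at least one contact strictly after the index
date and strictly before the readmission (cases) or within the 1050-day
follow-up horizon, inclusive (controls). Analyses are restricted to index
diagnoses with at least 1000 occurrences and to diagnosis combinations
*D* = (*d₁*, *d₂*) with at least 50 cases.

Interpretation choices where the design was genuinely open:

- **"Older than 50" is strict** (`age > min_age`); configurable.
- **Both readmission-window endpoints are inclusive**; "between 90 and 1050
  days" is ambiguous and symmetric inclusivity is the documented reading.
- **Controls are followed for 1050 days, not 1095**, so cases and controls
  share one horizon ("3 years" names both).
- **Admission rows sharing the index date are one stay** whose diagnosis
  set is the union; stay boundaries are otherwise undefined in claims rows.
- **A patient contributes every eligible index code** as a separate *d₁*.
- **The ≥50-case rule is applied within sex strata**, since every model is
  sex-stratified; the ≥1000-occurrence rule is applied jointly across sexes.
- **Robustness variants are pure configuration changes**: `short_window`
  sets the readmission window and follow-up to 540 days, `low_case_threshold`
  sets the combination minimum to 25, `no_age_floor` admits everyone under
  100. No code path differs between variants.

## Models

All fits are unpenalized maximum-likelihood logistic regressions
(statsmodels `Logit`), stratified by sex, with patient age in years as the
continuous covariate and probabilities evaluated at the **sex-specific mean
age of the study base** (configurable to the pooled mean):

- `P_diag(sex, d1)`: outcome = any readmission, universe = carriers of d₁.
- `P_spec(sex, s)`: outcome = at least one contact with s, universe = the
  sex stratum.
- `Q(sex, D, s)`: outcome = readmitted **with main diagnosis d₂** (a
  readmission for any other diagnosis counts as outcome 0; restricting the
  universe to readmitted patients is available behind a flag), covariates =
  (age, contact dummy). q₁ and q₀ evaluate the fit with the dummy set to 1
  and 0; RR = q₁/q₀ exactly.

A cell whose 2×2 contact × outcome table has an empty cell is skipped with a
logged reason; non-converged or separated fits are flagged and dropped from
aggregation with a logged count (never silently reported). The standard
error of a fitted probability is obtained by the delta method from the
coefficient covariance, `p(1−p)·√(xᵀVx)`.

## Aggregation and inference

`RR_diag(sex, d₁)` is the median of cell RRs over (d₂, s); `RR_spec(sex, s)`
the median over D. The attached SE is the SD of contributing cell RRs over
√n_cells and is absent for single-cell keys (the definition of a median's
SE is not canonical; this descriptive choice is labelled as such). Each
key's p-value compares its paired {q₁} and {q₀} values: the paired
differences are checked with a Kolmogorov–Smirnov test against a normal law
with estimated mean/SD at level 0.05 (a Lilliefors-style use: estimated
parameters make the nominal KS level conservative); a paired *t* test is
used when normality is not rejected, otherwise a two-sided sign test (zero
differences dropped; all-zero differences give p = 1). Keys with a single
cell or zero-variance differences go straight to the sign test. FDR is
controlled with Benjamini–Hochberg step-up at α = 0.05 **within each family**
(diagnosis-specific per sex; specialty-specific per sex); family structure
is configurable and a documented choice, not a claim about the only valid
grouping.

## Network backbone

Each readmitted patient in an included (D, s) incidence adds one unit of
flow to the directed edges d₁ → s and s → d₂ (a patient with several
eligible index codes counts once per incidence). Edges carry men/women
counts; the ratio uses an ∞ sentinel flagged `sex_ratio_defined=False` when
no women followed the link. The backbone is the **union** of the maximum
spanning tree (computed on the undirected view by Kruskal with ties broken
lexicographically by edge key, hence deterministic) and the edges passing
the **disparity filter**: at a degree-k endpoint with normalized edge weight
p the significance is (1 − p)^(k−1), and an edge passes when that value is
below the chosen level (default 0.05) at *either* endpoint; degree-1
endpoints contribute significance 1. Both the intersection mode and the
both-endpoints rule are available behind flags, since "overlapping" the two
filters admits either reading; the union is the common backbone recipe
(connectivity plus local significance). Node attributes record type
(diagnosis/specialty) and out-degree; no layout is computed.

## Synthetic-claims generator

The generator is first-class, tested code: it defines the statistical
structure the analysis assumes, with all effects configurable and a
closed-form oracle.

- Sex is Bernoulli (female fraction 0.58 by default); ages are truncated
  normal on [50, 100] with means 65 (men) / 68 (women) and SDs 9.7 / 11 —
  typical marginals of an elderly insured population.
- The observation window defaults to 2006-01-01…2012-03-31 with the index
  window through 2008-12-31.
- Each patient receives exactly one index admission, uniform in the index
  window, with a main diagnosis drawn from the catalog's prevalence weights
  and 0–4 secondary diagnoses drawn independently (duplicates dropped).
- Contact with specialty s is Bernoulli with logit
  `b[sex][s] + 0.01·age`; default intercepts span contact probabilities of
  roughly 10–55% at mean age across specialties.
- Readmission is Bernoulli with logit
  `b₀[sex][d₁] + 0.02·age + Σ_s γ[d₁][s]·contact_s` where d₁ is the main
  index diagnosis; γ is the ground-truth contact effect (default ln 0.8,
  mildly protective). The delay is uniform on [90, 1050] days and d₂ is
  drawn from a per-d₁ distribution **independently of contact**, so the
  true cell RR equals σ(η+γ)/σ(η) — the `P(d₂|d₁)` factor cancels — which
  is what `true_relative_risk` returns.
- Contacts of readmitted patients are placed uniformly strictly between
  index and readmission; contacts of controls uniformly within the
  follow-up horizon. Real data would show richer timing dependence between
  contact and readmission; no realism is claimed for timing beyond
  window membership.
- One `numpy` Generator seeded from the config drives all draws in a fixed
  order, so equal configs give byte-identical datasets.

What the generator does **not** emulate: mortality and censoring (the
emulated source excluded deceased individuals), repeated admissions beyond
the first readmission, contact counts beyond the binary flag, seasonal
patterns, coding error, and dependence between secondary diagnoses.
Passing tests therefore demonstrate correctness of the estimators under the
assumed logistic data-generating process — not robustness to the
misspecifications real claims data would add.

## Validation worlds and problem sizes

`readmitnet.worlds` fixes three canonical scenarios used by the test suite
and the acceptance script: a 50,000-patient single-diagnosis,
single-specialty world with γ = ln 0.5 (parameter recovery; the fitted model
coincides with the generating model, so the RR estimate must land within
±0.05 of the closed-form truth); 20,000-patient five-diagnosis,
two-specialty worlds with γ = 0 (null calibration of the BH-significant
fraction across 20 seeds, ~100 cells per world) and with γ = ln 0.5
(directionality: all significant aggregated RRs below 1). Brute-force
oracles re-derive combination counts and flow weights from the raw event
table of a 1,000-patient world, and check BH against the literal step-up
definition and the MST against exhaustive spanning-tree enumeration on
small random graphs. These sizes keep every check CPU-cheap while leaving
Monte-Carlo error well inside the asserted bands.

## Numerical notes and limitations

- Logistic fits use Newton iterations (statsmodels default) with
  convergence reported via flag; the intercept-only identity (fitted
  probability = empirical fraction) holds to ~1e-15.
- Dates are handled as pandas timestamps; day arithmetic is exact integer
  arithmetic on day differences. Files store ISO-8601 dates.
- Lexicographic tie-breaking makes the MST deterministic but not unique in
  the mathematical sense when weights tie; only total weight is
  optimal-unique.
- The Q-model for a combination cell is mildly misspecified when
  `P(d₂|d₁) < 1` (the scaled logistic is not logistic in age), which
  contributes the small negative bias visible in multi-diagnosis recovery
  summaries; the single-cell world is free of this and is the sharp
  recovery target.
- Aggregated p-values treat a key's cells as independent pairs, but cells
  sharing patients are correlated; the null-calibration check shows the
  realized false-positive fraction stays at the nominal level in the
  generator's worlds, not in all conceivable dependence structures.
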