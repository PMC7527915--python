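"""Apply the cohort rules to a claims dataset.

Eligibility (older than 50 at observation start, an admission within the
first three calendar years), index-stay extraction (earliest admission; its
main + secondary codes in A01-N99 become candidate index diagnoses d1),
readmission detection (earliest admission 90-1050 days after index supplies
the readmission diagnosis d2), binary contact flags per specialty, and the
list of diagnosis combinations D=(d1, d2) with enough cases to model.
"""

from readmitnet import CohortConfig, SimulationConfig, build_cohort, generate_dataset

ds = generate_dataset(SimulationConfig(n_patients=5000, seed=1))
# thresholds scaled to this small demo population (defaults: 1000 / 50)
cfg = CohortConfig(min_index_dx_count=200, min_combination_cases=25)
records, combinations, eligible = build_cohort(ds, cfg)

print(f"cohort records: {len(records)}")
print(f"readmitted: {records['readmitted'].sum()} "
      f"({records['readmitted'].mean():.1%} of the cohort)")
print(f"eligible index diagnoses (>= {cfg.min_index_dx_count} occurrences): {sorted(eligible)}")
print(f"\n{len(combinations)} diagnosis combinations with >= {cfg.min_combination_cases} cases; head:")
print(combinations.head(8).to_string(index=False))
# Each row counts readmitted patients of one sex whose index stay carried d1
# and whose readmission main diagnosis was d2.
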