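"""Age-adjusted readmission and contact probabilities.

P_diag(sex, d1) is the probability of any readmission for carriers of index
diagnosis d1, from a logistic fit of readmitted ~ age evaluated at the
stratum's mean age; P_spec(sex, s) is the analogous probability of at least
one contact with specialty s.
"""

from readmitnet import (
    CohortConfig,
    SimulationConfig,
    build_cohort,
    diagnosis_readmission_risk,
    generate_dataset,
    specialist_contact_probability,
)

ds = generate_dataset(SimulationConfig(n_patients=5000, seed=1))
records, _, eligible = build_cohort(
    ds, CohortConfig(min_index_dx_count=200, min_combination_cases=25)
)

print("P_diag (probability of any readmission, at mean age):")
for d1 in sorted(eligible):
    row = []
    for sex in ("m", "f"):
        est = diagnosis_readmission_risk(records, d1, sex)
        row.append(f"{sex}: {est.probability:.1%} (SE {est.se:.1%}, n={est.n_obs})")
    print(f"  {d1}  " + "   ".join(row))

print("\nP_spec (probability of at least one contact, at mean age):")
for s in ("internal medicine", "radiology", "psychiatry"):
    row = []
    for sex in ("m", "f"):
        est = specialist_contact_probability(records, s, sex)
        row.append(f"{sex}: {est.probability:.1%}")
    print(f"  {s:18s}" + "   ".join(row))
# Contact probabilities span a wide range across specialties, mirroring the
# configured logistic contact model.
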