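"""Generate a synthetic claims dataset and look at its marginals.

The generator draws an elderly insured population (truncated-normal ages per
sex), one index hospital stay per patient with main and secondary ICD-10
diagnoses, age-dependent specialist contacts, and readmissions whose
log-odds respond to age, sex, diagnosis and specialist contact.
"""

from readmitnet import SimulationConfig, generate_dataset

cfg = SimulationConfig(n_patients=5000, seed=1)
ds = generate_dataset(cfg)
ds.validate()

info = ds.events.groupby("patient_id").agg(sex=("sex", "first"), age=("age_at_start", "first"))
print(f"{len(ds.events)} events for {len(info)} patients")
print(f"female fraction: {(info.sex == 'f').mean():.3f}  (configured {cfg.female_fraction})")
print(info.groupby("sex")["age"].describe()[["mean", "std"]].round(1))
print("\nevent mix:")
print(ds.events["event_type"].value_counts())
# The female fraction and the per-sex age means/SDs should match the config;
# admissions outnumber patients because readmissions and secondary-diagnosis
# rows add to the index stays.
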