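"""Contact-dependent relative readmission risks and their recovery.

For each (sex, D=(d1,d2), specialty) cell the pipeline fits one logistic
model with age and a binary contact dummy, evaluates it at mean age with the
dummy on (q1) and off (q0), and reports RR = q1/q0.  Cell RRs are summarized
as medians per diagnosis and per specialty with a KS-gated paired t/sign
test and Benjamini-Hochberg FDR control.  Because the data are simulated,
every estimate can be compared with its closed-form ground truth.
"""

import math

from readmitnet import RunConfig, recovery_report, run_pipeline
from readmitnet.worlds import protective_world

# A world where every contact halves the readmission odds (gamma = ln 0.5).
sim, cohort = protective_world(n_patients=20_000, gamma=math.log(0.5), seed=3)
result = run_pipeline(RunConfig(sim=sim, cohort=cohort))

print(f"{len(result.cells)} (sex, D, s) cells fitted\n")
print("diagnosis-specific relative readmission risks (medians over d2 and s):")
print(result.agg_diagnosis.round(4).to_string(index=False))

table, summary = recovery_report(sim, result)
print(f"\nrecovery vs closed-form truth over {summary['n_cells']} cells: "
      f"bias {summary['bias']:+.4f}, RMSE {summary['rmse']:.4f}")
# rr_median values land near the true risk ratio implied by gamma; the
# significant flags survive BH correction within each sex's family.
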