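"""Relate tPSAD and pathology to biochemical recurrence.

Builds the quintile Kaplan-Meier / log-rank comparison of ln(tPSAD) and the
multivariable Cox model (EPE, SVI, margins, grade, ln tPSAD) on a simulated
cohort with planted hazard ratios.
"""

import numpy as np
import pandas as pd

from tpsad import (
    CohortSimParams,
    SurvivalData,
    apply_cohort_filters,
    compute_tpsad_cohort,
    km_curve,
    logrank_test,
    quintile_strata,
    simulate_cohort,
)
from tpsad.pipeline import fit_recurrence_cox

cohort = simulate_cohort(CohortSimParams(n_patients=4000), seed=3)
kept, _ = apply_cohort_filters(cohort)
results = compute_tpsad_cohort(kept)
table = kept.reset_index(drop=True).join(
    results.reset_index(drop=True)[["ln_tpsad", "valid_for_log"]]
)
table = table[table.valid_for_log]

strata = quintile_strata(table["ln_tpsad"].to_numpy())
data = SurvivalData(table["followup_time"].to_numpy(), table["recurrence"].to_numpy())
print("5-year recurrence-free survival by ln(tPSAD) quintile:")
for q in range(1, 6):
    mask = strata == q
    curve = km_curve(SurvivalData(data.times[mask], data.events[mask]))
    print(f"  Q{q}: S(60 months) = {curve.survival_at(60.0):.3f}  (n={mask.sum()})")
chi2, df, p = logrank_test(data, strata)
print(f"log-rank across quintiles: chi2={chi2:.2f}, df={df}, p={p:.3g}")

fit = fit_recurrence_cox(table, extra=table[["ln_tpsad"]])
print("\nmultivariable Cox model of biochemical recurrence:")
print(fit.summary().round(3).to_string())
# The planted adverse features carry HRs near their generative values
# (EPE 1.68, SVI 1.90, margins 2.12, GS7 1.97, GS8-10 5.28); ln(tPSAD)
# itself carries no independent planted hazard, so its HR hovers near 1 —
# its univariable association works through grade and stage.
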