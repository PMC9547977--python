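"""Survival modelling: Kaplan-Meier, log-rank, Cox with forward selection.

Excludes the trial-enrolled patients from overall-survival analysis,
compares wildtype vs mutant survival, and runs forward covariate
selection (entry cut-off 0.1) with KRAS status always reported in the
final model.
"""

from kraswt.survival import forward_select, km_curve, logrank, \
    prepare_records
from kraswt.synthetic_data import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(seed=1))
records = prepare_records(cohort.clinical)
print(f"{len(records)} records after exclusions "
      f"(planted log HR = {cohort.truth.true_log_hr:.3f}, "
      f"HR = {2.718281828 ** cohort.truth.true_log_hr:.2f})")

km = km_curve(records.reset_index(), "kras_wildtype")
for grp, sub in km.groupby("group"):
    name = "wildtype" if grp == 1 else "mutant"
    print(f"median survival, {name}: "
          f"{sub['median_survival'].iloc[0]:.1f} months")

lr = logrank(records.reset_index(), "kras_wildtype")
print(f"log-rank p = {lr.p_value:.4f}")

records["age_le_55"] = (records["age_at_diagnosis"] <= 55).astype(float)
selected, model = forward_select(records, ["age_le_55"], entry_p=0.1)
print(f"forward-selected covariates: {selected or 'none'}")
print(model.table[["covariate", "hr", "ci95_low", "ci95_high",
                   "wald_p"]].round(4).to_string(index=False))
# At n = 60 the wildtype hazard ratio estimate is noisy around the
# planted 0.25; the recovery tests use n = 300.
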