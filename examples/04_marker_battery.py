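"""Rank lipid markers by their association with incident events.

Generates a cohort whose hazard is log-linear in standardized eLDL-TG
(HR 1.24 per 1-SD over a 14-year horizon), then runs the comparison
battery: quintile Kaplan-Meier strata scored by the Gehan-Breslow
generalized Wilcoxon chi-square, single-marker ROC AUC, and adjusted
Cox hazard ratios per 1-SD.
"""
from eldltg import CohortSpec, HazardSpec, cox_fit, generate_cohort, marker_battery

cohort = generate_cohort(
    CohortSpec(n=20000, seed=123, hazard=HazardSpec(marker="eldl_tg", hr_per_sd=1.24))
)
print(f"{len(cohort)} subjects, {int(cohort['event'].sum())} events "
      f"over {cohort['follow_up'].max():.0f} years\n")

battery = marker_battery(
    cohort, ["eldl_tg", "ldl_c_sampson", "nonhdl_c", "rem_c", "sdldl_c"]
)
print("Quintile Wilcoxon chi-square and AUC, ranked:")
print(battery[["wilcoxon_chisq", "df", "auc"]].round(3).to_string())

res = cox_fit(
    cohort,
    covariates=["eldl_tg", "age", "sex", "race", "sbp", "bp_treated",
                "diabetes", "smoker"],
    standardize=["eldl_tg"],
)
hr = res.loc["eldl_tg"]
print(
    f"\nAdjusted Cox HR per 1-SD of eLDL-TG: {hr['hr']:.2f} "
    f"[95% CI {hr['ci_lower']:.2f}-{hr['ci_upper']:.2f}] "
    f"(truth used by the generator: 1.24)."
)
print(
    "The causal marker tops both rankings; correlated markers (Rem-C, "
    "sdLDL-C) inherit part of its signal, which is exactly the pattern "
    "the discordance analysis is designed to disentangle."
)
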