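"""Fit a multivariate Cox model and run AIC fast-backward selection.

Builds a cohort with three clinical confounders plus treatment, fits the
full proportional-hazards model, then lets backward elimination keep only
terms that earn their AIC cost.  The elimination trace shows what was
dropped and why.
"""

from radscreen import (
    Covariate,
    CoxModelSpec,
    RunConfig,
    apply_eligibility,
    fast_backward_aic,
    generate_cohort,
    standard_recovery_config,
)

sim = standard_recovery_config(seed=2, n_patients=2000)
expr, clin, _ = generate_cohort(sim)
cohort = apply_eligibility(expr, clin, RunConfig(seed=2), sim.schema)

spec = CoxModelSpec(
    "os_time",
    "os_event",
    (
        Covariate("radiotherapy"),
        Covariate("age_group", "categorical", "0"),
        Covariate("chemotherapy", "categorical", "0"),
        Covariate("stage", "categorical", "0"),
    ),
)
# note: this fit treats the clinical table as complete-case for simplicity;
# the discovery pipeline instead imputes and stacks (see example 03)
kept, fit, trace = fast_backward_aic(cohort.clinical.dropna(), spec)

print("retained terms:", [c.name for c in kept.covariates])
print(fit.summary[["hr", "ci_lower", "ci_upper", "p"]].round(3))
print(f"log partial likelihood {fit.log_likelihood:.1f}, AIC {fit.aic:.1f}")
for step in trace:
    print(f"dropped {step['removed']}: AIC {step['aic_before']:.1f} -> "
          f"{step['aic_after']:.1f}")
# An HR below 1 is protective.  All four genuine effects are retained.  The
# marginal HRs sit closer to 1 than the planted conditional values (age was
# planted at HR 2): the 70 planted gene effects are omitted from this model
# and act as frailty, which attenuates marginal hazard ratios — expected
# proportional-hazards behavior, not an estimation error.
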