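"""Full pipeline on one cohort: simulate, fit, and regress bias on hormones.

The generator injects a standardized effect of 0.38 of log-testosterone on
the response bias (and none on the discount rate kappa). After refitting
the SS-bias model per participant, standardized multiple regressions of
each recovered parameter on log-testosterone controlling for age show the
asymmetry: a positive testosterone slope for bias, a near-zero slope for
kappa. At n = 70 a single cohort detects the bias effect at the 5% level
only about half the time (the effect size is modest and age is collinear
with testosterone); `delaybias.recovery.effect_recovery_study` runs the
replicate-level version of this analysis.
"""

import numpy as np

from delaybias import (
    CohortConfig,
    FitConfig,
    fit_participant,
    regress_param_on_covariates,
    simulate_cohort,
)

cohort = simulate_cohort(
    CohortConfig(n_participants=70, seed=17, fit=FitConfig(n_restarts=4))
)
kappas, biases = [], []
for i, trials in enumerate(cohort.trials_by_participant.values()):
    fit = fit_participant(trials, "SS_BIAS", FitConfig(seed=i, n_restarts=6))
    kappas.append(fit.params.kappa)
    biases.append(fit.params.bias)

p = cohort.participants
print(f"cohort n={len(p)}: mean kappa_hat {np.mean(kappas):.3f} /day, "
      f"mean bias_hat {np.mean(biases):.1f} euros")
print(f"recovery correlation between fitted and generating bias: "
      f"{np.corrcoef(biases, p.sim_bias)[0, 1]:.2f}\n")

for name, values in (("bias", biases), ("log kappa", np.log(kappas))):
    res = regress_param_on_covariates(
        values, p.log_testosterone, p.age_months, outcome=name
    )
    t = res.predictor("log_testosterone")
    print(
        f"{name:>9} ~ log(T) + age:  b*_T = {t.b:+.2f}, "
        f"95% CI [{t.ci_low:+.2f}, {t.ci_high:+.2f}], p = {t.p:.3f}, VIF = {t.vif:.2f}"
    )
print(
    "\nThe testosterone slope concentrates on the bias parameter, not on "
    "kappa; whether its CI clears zero in any one cohort of 70 is "
    "borderline by construction."
)
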