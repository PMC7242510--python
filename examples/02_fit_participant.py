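"""Simulate one participant through the closed loop and refit the model.

A response-bias agent (hyperbolic discounting kappa = 0.08/day plus a
14.29-euro bias toward the smaller-sooner option, choice consistency
theta = 0.2) completes the 60-trial staircase; the hyperbolic model is fit
to that run; a tailored 64-trial scanner set is generated; the agent's
Bernoulli choices on it are refit with the SS-bias model by maximum
likelihood. Recovered parameters should sit near the generating values.
"""

import numpy as np

from delaybias import ChoiceRule, DiscountParams, FitConfig, fit_participant
from delaybias.recovery import simulate_tailored_participant

agent = DiscountParams.ss_bias(kappa=0.08, bias=14.29)
rule = ChoiceRule(theta=0.2)

trials = simulate_tailored_participant(
    agent, rule, np.random.SeedSequence(7), fit_config=FitConfig(seed=0)
)
ss_share = np.mean([t.chosen == "SS" for t in trials])
print(f"simulated 64 tailored trials; SS chosen on {ss_share:.0%} of them")

fit = fit_participant(trials, "SS_BIAS", FitConfig(seed=0))
print(f"log-likelihood at the MLE: {fit.loglik:.2f} nats (converged={fit.converged})")
print(f"recovered kappa: {fit.params.kappa:.4f} /day   (generating 0.08)")
print(f"recovered bias:  {fit.params.bias:.2f} euros  (generating 14.29)")
print(f"recovered theta: {fit.rule.theta:.3f} /euro  (generating 0.2)")
print(
    "\nSingle-participant estimates are noisy at 64 trials; cohort means "
    "are the quantity compared against the published group estimates."
)
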