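"""Evaluate the five discounting models on a common delay grid.

Each model maps a delay in days to a discount factor D(t) in (0, 1]; the
subjective value of a delayed amount is D(t) * amount. The printout shows
how steeply each model devalues a 20-euro reward over two months.
"""

from delaybias import DiscountParams, discount_factor, subjective_value, Prospect

MODELS = {
    "HYP       (kappa=0.08)": DiscountParams.hyperbolic(0.08),
    "HYP2      (kappa=0.08, sigma=0.7)": DiscountParams.hyperbolic2(0.08, 0.7),
    "DUAL      (d1=0.90, d2=0.98, w=0.3)": DiscountParams.dual(0.90, 0.98, 0.3),
    "SS_BIAS   (kappa=0.08, bias=14.29)": DiscountParams.ss_bias(0.08, 14.29),
}

delays = [0, 7, 15, 30, 60]
print("discount factor D(t)")
print(f"{'model':<38}" + "".join(f"t={d:>3}d " for d in delays))
for label, params in MODELS.items():
    row = "".join(f"{float(discount_factor(params, d)):6.3f} " for d in delays)
    print(f"{label:<38}{row}")

print()
print("subjective value of 20 euros at 30 days (U = D * A):")
for label, params in MODELS.items():
    u = subjective_value(Prospect(20.0, 30.0), params)
    print(f"  {label:<38}{u:6.2f} euros")
print(
    "\nNote: the response-bias models discount hyperbolically; their bias "
    "acts inside the choice rule, not on the valuation itself."
)
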