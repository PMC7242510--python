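# Methods

## The behavioural model family

A binary intertemporal choice offers a smaller-sooner prospect (amount
A_SS at delay t_SS, delay 0 meaning "today") against a larger-later one
(A_LL at t_LL > t_SS, A_LL > A_SS). All models score prospects by
discounted utility U = D(t)·A and choose stochastically through a logistic
rule on the value difference,

    P(LL) = 1 / (1 + exp(−θ·(V_LL − (V_SS + bias)))),

with θ ≥ 0 the choice consistency (inverse temperature, 1/euro; θ = 0 is
random choice). Five discount/bias configurations are implemented:
one-parameter hyperbolic (`HYP`, D = 1/(1+κt)); two-parameter hyperbolic
(`HYP2`, D = (1+κt)^−σ, σ modulating short- vs long-delay sensitivity);
a dual-system mixture of two exponentials (`DUAL`,
D = ωδ₁^t + (1−ω)δ₂^t with δ₁ < δ₂ enforced so one system is strictly
more impatient); and two response-bias models that keep hyperbolic
valuation but add a constant (in euros of subjective value) to the SS
option inside the choice rule — on every trial (`SS_BIAS`) or only when
the SS option is available today (`IMM_BIAS`, gated on t_SS == 0 exactly,
since the task has exactly two conditions). A positive bias favours SS
choices independently of the amounts and delays; that independence from
valuation is the scientific point of the bias models.

Time is measured in days for every model, including the dual-system
exponents; amounts in euros. Probabilities are computed with an
overflow-safe logistic and clipped to [1e−12, 1 − 1e−12] before any
logarithm.

## Maximum-likelihood fitting

Each participant × model fit minimises the summed negative log-likelihood
of the scorable trials (responses SS/LL; MISSING responses contribute
nothing). The search runs in an unconstrained transformed space — κ, σ, θ
log-transformed; ω by logit; the dual-system pair as δ₂ = logistic(x) and
δ₁ = δ₂·logistic(u), which guarantees the ordering; the bias through a
scaled tanh with soft bounds ±50 € — using Nelder–Mead simplex from 10
Latin-hypercube starting points over plausible ranges (κ ∈ [1e−4, 1]/day,
θ ∈ [1e−3, 5]/€, bias ∈ [−50, 50] €, δ ∈ [0.5, 0.999], ω ∈ [0.05, 0.95]),
objective tolerance 1e−8. The bias bound matters: when θ is small the
likelihood is flat along the θ·bias ridge (in the limit the model
degenerates to a fixed-rate Bernoulli), and an unbounded bias can drift
arbitrarily far along it. Refits with the same seed are bit-identical.

All-SS or all-LL choice vectors leave θ (and with it everything else)
unidentified; such fits are still returned but flagged non-identifiable
with parameters at a bound, and group summaries exclude participants whose
fits error out. A configurable minimum of 20 scorable trials is enforced.
Group-level summaries report each parameter's mean with its standard error
of the mean (SD/√N) and the pairwise correlations between per-participant
estimates.

## Model comparison

The group deviance is G² = 2·Σ_participants −loglik at the per-participant
MLEs, and BIC = G² + p·ln(n). Because every participant carries their own
parameter vector, the default penalty counts the total number of free
parameters (N participants × per-model count, against n = total scorable
choices). Penalising only the per-model count makes a spurious
per-participant parameter nearly free — its expected deviance gain grows
with N while the penalty stays fixed — so that convention is available
only as an explicit override (`param_counting="per_model"`, `bic_n_obs`),
useful for emulating reporting styles that print per-model penalties. Ties
in BIC rank break toward fewer parameters.

Predictive accuracy uses k-fold cross-validation within participant
(default 8 folds over 64 trials), stratified by the NOW/LATER condition
and seeded per participant (a CRC of the participant id mixed with the
config seed), which makes the score invariant to cohort ordering. The
model is refit on k−1 folds and the held-out log-likelihood summed; the
reported score is the cohort mean per participant, so higher (closer to
zero) is better. A training fold reduced to a single choice class cannot
support a refit and is merged into the following fold.

## Staircase and tailored design

The pre-scanner staircase fixes the SS option at 10 € today and titrates
the LL amount toward indifference over 60 trials. The LL delay range of
15–60 days is split into four bins (15 trials each, interleaved in random
order, delay drawn uniformly within the bin); each bin holds a bisection
bracket from 10 € to a 300 € cap — choosing LL lowers the bin's upper
bound, choosing SS raises its lower bound, the next proposal is the
midpoint. For a noise-free hyperbolic agent the bracket midpoint converges
geometrically to the analytic indifference amount 10·(1+κd). The
hyperbolic model fit to the 60 staircase choices supplies κ̂ for design
generation. Note that for an agent whose true process includes a response
bias, κ̂ systematically exceeds the generating κ: the hyperbolic fit
absorbs the bias into steeper discounting. This is expected and is exactly
what makes the κ̂-tailored design sit near the agent's *effective*
indifference.

The scanner design draws 64 trials, exactly 32 with the SS option today
and 32 with both options in the future (SS delay uniform 2–15 days). For
each trial the targeted value difference V_LL − V_SS under κ̂ is uniform
on ±10 €, and the LL amount is solved from it. Three design choices are
deliberate, and were made on identifiability grounds (the additive bias,
the multiplicative discount and θ must be separable from 64 binary
responses):

* the value-difference band is denominated in euros, not as a fraction of
  V_SS, so that predicted choice probabilities span the informative range
  of the logistic (at θ ≈ 0.2/€, ±10 € maps to P(LL) ≈ 0.12–0.88) instead
  of clustering at one half;
* SS amounts are log-uniform over 2.5–80 €: the bias adds a constant
  number of euros while discounting scales with the amount, so wide
  multiplicative amount spread decorrelates the two;
* LL delays take the extreme values {15, 60} days (and the LATER-condition
  delay gaps {13, 45} days), maximising the delay contrast that pins κ.

A band concentrated tightly at indifference (e.g. a ±20%-of-V_SS band)
leaves the likelihood ridge toward the degenerate Bernoulli limit almost
unpenalised and produces a strongly right-skewed bias estimator whose
cohort mean overshoots the generating value by upwards of 50%; the
euro-denominated band with amount and delay spread brings the estimator
close to its Cramér–Rao floor (SD ≈ 4.6 € at 64 trials) with negligible
mean skew, while still yielding the intended roughly even choice split
(simulated SS share ≈ 56–58%). Solved LL amounts are rounded to 0.50 €,
floored at SS + 0.50 € (the patient-κ̂ limit simply shrinks amount gaps)
and capped at 300 €; cap saturation is logged as a warning.

## Synthetic cohorts

Covariates are generated from a trivariate Gaussian core with target
correlations (age–logT .73, age–PDS .80, T–PDS .76), mapped to: age in
months (mean 156.99, SD 19.11, clipped to the 120–191 month recruitment
window, with the pre-clip parameters solved from the censored-normal
moment equations so the published mean and SD survive the clipping — the
same correction is applied to the PDS scale bounds); salivary
testosterone through a moment-matched log-normal (mean
78.29, SD 53.90 pmol/L — right-skewed, as hormone concentrations are),
with two "samples" generated around each participant's level so their
log-scale correlation matches the reported inter-assay correlation of
0.73, the analysis value being the mean of the two; and a pubertal
development score (mean 1.82, SD 0.71, clipped to the 1–4 scale range).
The discrete item structure of the pubertal questionnaire is not modelled,
only a continuous composite.

Generating choice parameters centre on the published group-mean estimates:
bias = 14.29 + 23.43·(0.38·z_logT + √(1−0.38²)·ε) euros, so the
standardized slope of generating bias on log-testosterone is 0.38 by
construction (configurable; 0 gives a null generator); κ log-normal with
mean 0.08/day and SD 0.0251 (the between-participant SDs are the published
standard errors × √70, since only SEs are reported); θ fixed at 0.2/€.
Generating biases are clipped at ±49 € so all truth lies inside the
fitting bounds; the clip moves the cohort mean by under 0.3 €. Choices are
simulated either through the full closed loop (each agent runs the
staircase, gets its own tailored design, and answers by Bernoulli draws
from its choice rule) or on a shared fixed grid tailored to the group-mean
κ.

What the generator does *not* emulate: reaction times and the trial timing
(inter-trial jitter and the 6 s response window are metadata only),
missing responses, real assay noise beyond the two-sample correlation,
discrete questionnaire items, and any physiological mechanism — the
testosterone→bias slope is injected statistically, not mechanistically.
Passing recovery tests therefore validates the estimation and analysis
chain, not any claim about hormones in real adolescents.

## Recovery studies and the sizes used

Three validation studies are bundled (`delaybias.recovery`) and exercised
by the test suite at the following problem sizes, chosen to keep the full
suite at desk scale:

* **Group-mean parameter recovery**: 200 identical SS-bias agents
  (κ = 0.08, bias = 14.29, θ = 0.2) through the closed loop; cohort-mean
  κ̂ recovers the generating κ within 5% and mean bias within 10%. This is
  also what `scripts/acceptance.py` recomputes (seeded from its `--seed`).
* **Model recovery**: 50 replicate cohorts of 8 participants generated
  from the SS-bias process; the generating model wins the BIC comparison
  against all four alternatives in well over 60% of replicates (observed
  margins are large, ΔBIC in the hundreds), and hyperbolic-generated
  cohorts do not spuriously prefer the bias model (the total-parameter BIC
  penalty exceeds the chance deviance gain).
* **Effect recovery**: cohorts of 70 with the 0.38 testosterone→bias
  effect; 50 replicates for the effect arm, 40 for the null arm. The
  per-replicate detection rate (bias CI excluding zero, controlling age)
  is about 0.5–0.6 — the effect size combined with the age–testosterone
  collinearity (VIF ≈ 2) makes single cohorts of 70 borderline by
  construction — while the testosterone CI for κ (no injected effect)
  covers zero at close to the nominal rate, as does the bias CI under the
  null generator.

## Numerical notes and limitations

* Likelihood terms are computed as log(1+e^x) via `logaddexp` and capped
  consistently with the probability clipping; the brute-force per-trial
  oracle agrees to 1e−10.
* Nelder–Mead is derivative-free and robust to the likelihood's plateaus;
  multistart handles multimodality. Fits are deterministic given a seed,
  and near-identical log-likelihoods across seeds on well-conditioned data.
* The per-participant bias MLE at 64 trials and θ = 0.2 retains a small
  positive finite-sample skew (a consequence of the θ·bias ridge) of
  roughly +2–4% on the cohort mean; it vanishes with more trials (at 640
  trials the mean recovers the truth to under 1%).
* Quartile boundaries and IQR fences use linear-interpolation quantiles;
  the subsample keeps [Q1, Q3] inclusive; the outlier fence multiplier is
  Tukey's 1.5.
* Standard errors in regressions are plain normal-theory OLS; no
  multiple-testing correction is applied anywhere, matching the analysis
  style the package reproduces.
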