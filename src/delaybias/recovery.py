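"""Parameter- and model-recovery simulation studies.

Recovery studies are the standard validation tool for cognitive models:
choices are simulated from known parameters under the task's actual design
pipeline, the models are refit, and the estimates are compared with the
generating truth. Three studies are provided:

* :func:`recover_group_means` - simulate a cohort of identical agents
  through the full closed loop (staircase -> tailored scanner set ->
  Bernoulli choices), refit, and report cohort-mean estimates of the
  discount rate and response bias;
* :func:`model_recovery_study` - generate replicate cohorts from one model
  and ask how often that model wins the BIC comparison;
* :func:`effect_recovery_study` - inject a standardized testosterone
  effect on the generating bias, run the simulate -> fit -> regress
  pipeline, and record how often the regression detects (or correctly
  fails to detect) the effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .models import ChoiceRule, DiscountParams, MODEL_IDS
from .fitting import FitConfig, fit_participant
from .staircase import (
    ScannerConfig,
    StaircaseConfig,
    generate_scanner_set,
    run_staircase,
    simulate_agent_choice,
)
from .cohort import CohortConfig, simulate_cohort
from .comparison import ComparisonConfig, compare_models
from .analysis import regress_param_on_covariates

__all__ = [
    "GroupRecovery",
    "recover_group_means",
    "simulate_tailored_participant",
    "model_recovery_study",
    "effect_recovery_study",
    "EffectRecovery",
]


def simulate_tailored_participant(
    params: DiscountParams,
    rule: ChoiceRule,
    seed_sequence: np.random.SeedSequence,
    staircase_config: Optional[StaircaseConfig] = None,
    scanner_config: Optional[ScannerConfig] = None,
    fit_config: Optional[FitConfig] = None,
):
    """One agent through the closed loop; returns its 64 scored trials."""
    s1, s2, s3 = (int(x % 2**31) for x in seed_sequence.generate_state(3))
    run = run_staircase(
        params, rule, seed=s1, config=staircase_config, fit_config=fit_config
    )
    design = generate_scanner_set(run.kappa_hat, seed=s2, config=scanner_config)
    rng = np.random.default_rng(s3)
    return [t.with_choice(simulate_agent_choice(t, params, rule, rng)) for t in design]


@dataclass
class GroupRecovery:
    n_participants: int
    kappa_true: float
    bias_true: float
    kappa_mean: float
    bias_mean: float
    kappa_estimates: np.ndarray
    bias_estimates: np.ndarray


def recover_group_means(
    n_participants: int,
    kappa: float,
    bias: float,
    theta: float,
    seed: int,
    fit_config: Optional[FitConfig] = None,
) -> GroupRecovery:
    """Cohort of identical response-bias agents: closed-loop simulate + refit.

    Every agent shares the same generating parameters; the returned means
    are the cohort averages of the per-participant maximum-likelihood
    estimates under the SS-bias model.
    """
    params = DiscountParams.ss_bias(kappa, bias)
    rule = ChoiceRule(theta)
    cfg = fit_config or FitConfig()
    ks, bs = [], []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_participants)):
        trials = simulate_tailored_participant(params, rule, child, fit_config=cfg)
        fit = fit_participant(trials, "SS_BIAS", dataclasses.replace(cfg, seed=i))
        ks.append(fit.params.kappa)
        bs.append(fit.params.bias)
    ks = np.asarray(ks)
    bs = np.asarray(bs)
    return GroupRecovery(
        n_participants=n_participants,
        kappa_true=kappa,
        bias_true=bias,
        kappa_mean=float(ks.mean()),
        bias_mean=float(bs.mean()),
        kappa_estimates=ks,
        bias_estimates=bs,
    )


def model_recovery_study(
    generating_model: str,
    candidate_models: Sequence[str] = MODEL_IDS,
    n_replicates: int = 50,
    n_participants: int = 8,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
) -> dict:
    """Fraction of replicate cohorts in which each model wins by BIC.

    Cohorts are drawn from the synthetic-cohort generator with
    ``generating_model`` as the choice process (heterogeneous parameters
    around the group means).
    """
    if generating_model not in MODEL_IDS:
        raise ValueError(f"unknown generating model {generating_model!r}")
    fcfg = fit_config or FitConfig(n_restarts=6)
    wins = {m: 0 for m in candidate_models}
    for r in range(n_replicates):
        cohort = simulate_cohort(
            CohortConfig(
                n_participants=n_participants,
                seed=seed + 104729 * (r + 1),
                model_id=generating_model,
                fit=fcfg,
            )
        )
        table = compare_models(
            cohort.trials_by_participant,
            candidate_models,
            ComparisonConfig(include_cv=False, seed=seed + r, fit=fcfg),
        )
        wins[table.best_model] += 1
    return {m: wins[m] / n_replicates for m in candidate_models}


@dataclass
class EffectRecovery:
    effect: float
    n_replicates: int
    bias_ci_excludes_zero: float  # fraction of replicates
    bias_ci_covers_zero: float
    kappa_ci_covers_zero: float
    bias_slopes: np.ndarray


def effect_recovery_study(
    effect: float,
    n_replicates: int = 40,
    n_participants: int = 70,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
    staircase_fit_config: Optional[FitConfig] = None,
) -> EffectRecovery:
    """Simulate -> fit -> regress replicates and score the testosterone CIs.

    For each replicate a full cohort is generated with the given
    standardized testosterone -> bias effect, the SS-bias model is refit per
    participant, and the recovered bias and log-kappa are each regressed on
    log-testosterone controlling for age.
    """
    fcfg = fit_config or FitConfig(n_restarts=6)
    scfg = staircase_fit_config or FitConfig(n_restarts=4)
    excl, cover, kcover, slopes = [], [], [], []
    for r in range(n_replicates):
        cohort = simulate_cohort(
            CohortConfig(
                n_participants=n_participants,
                seed=seed + 15485863 * (r + 1),
                effect_bias=effect,
                fit=scfg,
            )
        )
        ks, bs = [], []
        for i, trials in enumerate(cohort.trials_by_participant.values()):
            fit = fit_participant(
                trials, "SS_BIAS", dataclasses.replace(fcfg, seed=i)
            )
            ks.append(fit.params.kappa)
            bs.append(fit.params.bias)
        p = cohort.participants
        res_b = regress_param_on_covariates(
            bs, p.log_testosterone, p.age_months, outcome="bias"
        )
        res_k = regress_param_on_covariates(
            np.log(ks), p.log_testosterone, p.age_months, outcome="log_kappa"
        )
        tb = res_b.predictor("log_testosterone")
        tk = res_k.predictor("log_testosterone")
        excl.append(tb.ci_low > 0 or tb.ci_high < 0)
        cover.append(tb.ci_low <= 0 <= tb.ci_high)
        kcover.append(tk.ci_low <= 0 <= tk.ci_high)
        slopes.append(tb.b)
    return EffectRecovery(
        effect=effect,
        n_replicates=n_replicates,
        bias_ci_excludes_zero=float(np.mean(excl)),
        bias_ci_covers_zero=float(np.mean(cover)),
        kappa_ci_covers_zero=float(np.mean(kcover)),
        bias_slopes=np.asarray(slopes),
    )
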