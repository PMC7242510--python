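"""Synthetic cohorts of adolescent participants for end-to-end testing.

Real participant data for this kind of study (male adolescents, 10-15 y,
salivary testosterone, 64 intertemporal choices each) are typically not
shareable, so this module generates cohorts whose covariate structure and
choice behaviour emulate the published summary statistics:

* age ~ N(156.99, 19.11) months, clipped to the 10-15 y recruitment window;
* salivary testosterone log-normal with mean 78.29 and SD 53.90 pmol/L
  (right-skewed), measured twice with an inter-sample correlation of 0.73
  and averaged;
* Pubertal Development Scale score ~ N(1.82, 0.71) clipped to [1, 4];
* pairwise correlations age-T = .73, T-PDS = .76, age-PDS = .80 via a
  Gaussian copula on (z_age, z_logT, z_pds);
* generating choice parameters centred on the published group means
  (kappa = 0.08 /day, bias = 14.29 euros, theta = 0.2 /euro) with a
  standardized effect of log-testosterone on the bias parameter
  (default 0.38) and none on kappa.

Choices are simulated either through the full closed loop (staircase ->
fitted kappa -> tailored scanner set -> Bernoulli choices) or on a shared
fixed grid tailored to the group-mean discount rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .models import ChoiceRule, DiscountParams
from .trials import ChoiceTrial, trials_to_frame
from .fitting import FitConfig
from .staircase import (
    ScannerConfig,
    StaircaseConfig,
    generate_scanner_set,
    run_staircase,
    simulate_agent_choice,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "simulate_covariates",
    "assign_generating_params",
    "simulate_choices",
    "simulate_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for a synthetic cohort.

    Covariate moments and correlations follow the published cohort summary;
    the generating choice parameters are the published group-mean estimates.
    ``effect_bias`` / ``effect_kappa`` are standardized slopes of
    log-testosterone on the generating bias / log-kappa.
    """

    n_participants: int = 70
    seed: int = 0
    # covariates
    age_mean: float = 156.99
    age_sd: float = 19.11
    age_range: Tuple[float, float] = (120.0, 191.0)
    t_mean: float = 78.29
    t_sd: float = 53.90
    pds_mean: float = 1.82
    pds_sd: float = 0.71
    pds_range: Tuple[float, float] = (1.0, 4.0)
    r_age_t: float = 0.73
    r_age_pds: float = 0.80
    r_t_pds: float = 0.76
    r_intersample: float = 0.73
    # generating behaviour
    model_id: str = "SS_BIAS"
    kappa_mean: float = 0.08
    kappa_sd: float = 0.0251  # published SE 0.003 * sqrt(70)
    bias_mean: float = 14.29
    bias_sd: float = 23.43  # published SE 2.80 * sqrt(70)
    bias_clip: float = 49.0  # keep truth inside the fitting bounds
    theta: float = 0.2
    theta_sd: float = 0.0
    effect_bias: float = 0.38
    effect_kappa: float = 0.0
    design_source: str = "staircase_loop"  # or "fixed_grid"
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    scanner: ScannerConfig = field(default_factory=ScannerConfig)
    fit: FitConfig = field(default_factory=FitConfig)

    def correlation_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_age_t, self.r_age_pds],
                [self.r_age_t, 1.0, self.r_t_pds],
                [self.r_age_pds, self.r_t_pds, 1.0],
            ]
        )


@dataclass
class Cohort:
    """A simulated cohort: covariates + generating parameters + trials."""

    config: CohortConfig
    participants: pd.DataFrame
    trials_by_participant: Dict[str, List[ChoiceTrial]]

    def trials_frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                trials_to_frame(trials, pid)
                for pid, trials in self.trials_by_participant.items()
            ],
            ignore_index=True,
        )

    def write(self, participants_path, trials_path) -> None:
        self.participants.to_csv(participants_path, index=False)
        self.trials_frame().to_csv(trials_path, index=False)


def _censored_normal_params(
    target_mean: float, target_sd: float, lo: float, hi: float
) -> Tuple[float, float]:
    """Pre-clip (mu, sigma) such that clip(N(mu, sigma), lo, hi) has the
    target mean and SD.

    Clipping to a finite window shrinks the SD (and shifts the mean when
    the window is asymmetric); solving the censored-normal moment equations
    keeps the published moments exact despite the range constraint.
    """
    from scipy.optimize import fsolve
    from scipy.stats import norm

    def censored_moments(mu, sigma):
        a = (lo - mu) / sigma
        b = (hi - mu) / sigma
        pa, pb = norm.cdf(a), norm.cdf(b)
        fa, fb = norm.pdf(a), norm.pdf(b)
        mid = pb - pa
        m1 = lo * pa + hi * (1 - pb) + mu * mid + sigma * (fa - fb)
        m2 = (
            lo**2 * pa
            + hi**2 * (1 - pb)
            + (mu**2 + sigma**2) * mid
            + 2 * mu * sigma * (fa - fb)
            + sigma**2 * (a * fa - b * fb)
        )
        return m1, math.sqrt(max(m2 - m1**2, 1e-12))

    def equations(x):
        m, s = censored_moments(x[0], abs(x[1]))
        return [m - target_mean, s - target_sd]

    sol = fsolve(equations, [target_mean, target_sd])
    mu0, sigma0 = float(sol[0]), abs(float(sol[1]))
    m, s = censored_moments(mu0, sigma0)
    if abs(m - target_mean) > 0.05 * abs(target_mean) or abs(s - target_sd) > 0.05 * target_sd:
        return target_mean, target_sd  # fall back to naive parameters
    return mu0, sigma0


def simulate_covariates(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw the covariate table (age, two testosterone samples, PDS).

    The three covariates share a trivariate standard-normal core with the
    target correlation matrix; testosterone is mapped through a moment-
    matched log-normal (right-skewed marginal), age and PDS through affine
    maps with clipping to their plausible ranges.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    corr = config.correlation_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    n = config.n_participants
    if n < 2:
        raise ValueError("n_participants must be >= 2")
    z = rng.standard_normal((n, 3)) @ chol.T
    z_age, z_logt, z_pds = z[:, 0], z[:, 1], z[:, 2]

    age_mu, age_sigma = _censored_normal_params(
        config.age_mean, config.age_sd, *config.age_range
    )
    age = np.clip(age_mu + age_sigma * z_age, *config.age_range)
    # log-normal moment matching: exp(mu + s*z) has the target mean and SD
    s2 = math.log(1.0 + (config.t_sd / config.t_mean) ** 2)
    mu = math.log(config.t_mean) - s2 / 2.0
    t_mean_i = np.exp(mu + math.sqrt(s2) * z_logt)
    # two samples around the participant mean with the target inter-sample
    # correlation on the log scale: shared variance s2, sample noise v
    r = config.r_intersample
    v = s2 * (1.0 / r - 1.0)
    e1 = rng.standard_normal(n) * math.sqrt(v)
    e2 = rng.standard_normal(n) * math.sqrt(v)
    t_s1 = t_mean_i * np.exp(e1 - v / 2.0)
    t_s2 = t_mean_i * np.exp(e2 - v / 2.0)
    pds_mu, pds_sigma = _censored_normal_params(
        config.pds_mean, config.pds_sd, *config.pds_range
    )
    pds = np.clip(pds_mu + pds_sigma * z_pds, *config.pds_range)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age_months": age,
            "testosterone_s1": t_s1,
            "testosterone_s2": t_s2,
            "testosterone_mean": t_mean_i,
            "log_testosterone": np.log(t_mean_i),
            "pds": pds,
        }
    )


def assign_generating_params(
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Attach generating choice parameters (``sim_`` columns) to a cohort.

    The generating bias is ``bias_mean + bias_sd * (effect * z_logT +
    sqrt(1 - effect^2) * noise)`` so its standardized regression slope on
    log-testosterone equals ``effect_bias`` by construction; kappa is
    log-normal around ``kappa_mean`` with an analogous (default zero)
    testosterone effect on log-kappa.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = len(covariates)
    logt = covariates["log_testosterone"].to_numpy()
    z_logt = (logt - logt.mean()) / logt.std(ddof=0)

    eb = config.effect_bias
    bias = config.bias_mean + config.bias_sd * (
        eb * z_logt + math.sqrt(max(0.0, 1.0 - eb**2)) * rng.standard_normal(n)
    )
    bias = np.clip(bias, -config.bias_clip, config.bias_clip)

    s2k = math.log(1.0 + (config.kappa_sd / config.kappa_mean) ** 2)
    muk = math.log(config.kappa_mean) - s2k / 2.0
    ek = config.effect_kappa
    zk = ek * z_logt + math.sqrt(max(0.0, 1.0 - ek**2)) * rng.standard_normal(n)
    kappa = np.exp(muk + math.sqrt(s2k) * zk)

    if config.theta_sd > 0:
        s2t = math.log(1.0 + (config.theta_sd / config.theta) ** 2)
        theta = np.exp(
            math.log(config.theta) - s2t / 2.0 + math.sqrt(s2t) * rng.standard_normal(n)
        )
    else:
        theta = np.full(n, config.theta)

    out = covariates.copy()
    out["sim_model_id"] = config.model_id
    out["sim_kappa"] = kappa
    out["sim_bias"] = bias
    out["sim_theta"] = theta
    return out


def _participant_params(row, config: CohortConfig) -> Tuple[DiscountParams, ChoiceRule]:
    model_id = row["sim_model_id"]
    if model_id in ("SS_BIAS", "IMM_BIAS"):
        params = DiscountParams(model_id, kappa=row["sim_kappa"], bias=row["sim_bias"])
    elif model_id == "HYP":
        params = DiscountParams.hyperbolic(row["sim_kappa"])
    else:
        raise ValueError(f"unsupported generating model {model_id!r}")
    return params, ChoiceRule(float(row["sim_theta"]))


def simulate_choices(
    params: DiscountParams,
    rule: ChoiceRule,
    design_source: str,
    seed: int,
    config: Optional[CohortConfig] = None,
    fixed_design: Optional[List[ChoiceTrial]] = None,
) -> List[ChoiceTrial]:
    """Simulate one participant's 64 scanner choices.

    ``staircase_loop`` runs the full closed loop: the agent performs the
    staircase, the hyperbolic model is fit to that run, a tailored scanner
    set is generated from the fitted kappa, and choices on it are Bernoulli
    draws from the agent's choice rule. ``fixed_grid`` scores a shared
    pre-built design (``fixed_design``).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    if design_source == "staircase_loop":
        run = run_staircase(
            params, rule, seed=seed + 1, config=cfg.staircase, fit_config=cfg.fit
        )
        design = generate_scanner_set(run.kappa_hat, seed=seed + 2, config=cfg.scanner)
    elif design_source == "fixed_grid":
        if fixed_design is None:
            design = generate_scanner_set(
                cfg.kappa_mean, seed=seed + 2, config=cfg.scanner
            )
        else:
            design = fixed_design
    else:
        raise ValueError(f"unknown design_source {design_source!r}")
    from .models import _pll

    p_ll = _pll(
        np.array([t.ss.amount for t in design]),
        np.array([t.ss.delay for t in design]),
        np.array([t.ll.amount for t in design]),
        np.array([t.ll.delay for t in design]),
        params,
        rule,
    )
    draws = rng.random(len(design)) < p_ll
    return [
        t.with_choice("LL" if ll else "SS") for t, ll in zip(design, draws)
    ]


def simulate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Generate a full cohort: covariates, generating parameters, choices."""
    cfg = config or CohortConfig()
    seeds = np.random.SeedSequence(cfg.seed)
    cov_seed, param_seed, trial_seed = seeds.spawn(3)
    covariates = simulate_covariates(cfg, np.random.default_rng(cov_seed))
    participants = assign_generating_params(
        covariates, cfg, np.random.default_rng(param_seed)
    )
    fixed_design = None
    if cfg.design_source == "fixed_grid":
        fixed_design = generate_scanner_set(
            cfg.kappa_mean,
            seed=int(trial_seed.generate_state(1)[0] % (2**31)),
            config=cfg.scanner,
        )
    trial_children = trial_seed.spawn(len(participants))
    trials_by_participant: Dict[str, List[ChoiceTrial]] = {}
    for child, (_, row) in zip(trial_children, participants.iterrows()):
        params, rule = _participant_params(row, cfg)
        pid = row["participant_id"]
        trials_by_participant[pid] = simulate_choices(
            params,
            rule,
            cfg.design_source,
            seed=int(child.generate_state(1)[0] % (2**31)),
            config=cfg,
            fixed_design=fixed_design,
        )
    return Cohort(
        config=cfg,
        participants=participants,
        trials_by_participant=trials_by_participant,
    )
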