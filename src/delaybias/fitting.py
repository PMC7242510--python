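"""Per-participant maximum-likelihood estimation of the discounting models.

Each participant's trial-level choices are scored with the logistic choice
rule, and the joint vector of discount parameters plus inverse temperature
theta is estimated by minimising the negative log-likelihood with a
derivative-free simplex (Nelder–Mead) search. Searches run in a transformed,
unconstrained space:

* ``kappa``, ``sigma``, ``theta`` on the log scale (positivity);
* ``omega`` through a logit (stays in (0, 1));
* the dual-system retention factors as ``delta2 = logistic(x)`` and
  ``delta1 = delta2 * logistic(u)``, which enforces ``delta1 < delta2`` by
  construction;
* ``bias`` through a scaled tanh soft bound (default ±50 euros of value,
  covering the plausible range while preventing the
  bias from running away when theta is near zero and the likelihood becomes
  flat along the theta*bias ridge).

Multiple restarts are drawn from a Latin-hypercube over plausible parameter
ranges; the best local optimum is reported. MISSING responses contribute
nothing to the likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .models import (
    MODEL_IDS,
    PROB_EPS,
    ChoiceRule,
    DiscountParams,
    _logistic,
)
from .trials import ChoiceTrial

__all__ = [
    "FitConfig",
    "FitResult",
    "GroupFit",
    "negloglik",
    "fit_participant",
    "fit_group",
]

log = logging.getLogger(__name__)

_NLL_CAP = -math.log(PROB_EPS)  # per-trial cap, matches probability clipping


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for maximum-likelihood fitting.

    ``n_restarts`` Latin-hypercube starting points are drawn from the ranges
    below (rates and theta log-uniform); each start is refined by
    Nelder–Mead with function tolerance ``ftol``.
    """

    n_restarts: int = 10
    seed: int = 0
    ftol: float = 1e-8
    max_iter: int = 600
    min_trials: int = 20
    kappa_range: tuple = (1e-4, 1.0)
    sigma_range: tuple = (0.2, 5.0)
    theta_range: tuple = (1e-3, 5.0)
    bias_range: tuple = (-50.0, 50.0)
    delta_range: tuple = (0.5, 0.999)
    omega_range: tuple = (0.05, 0.95)
    bias_bound: float = 50.0


@dataclass
class FitResult:
    """Outcome of one participant x model maximum-likelihood fit."""

    model_id: str
    params: DiscountParams
    rule: ChoiceRule
    loglik: float
    n_trials_used: int
    converged: bool
    n_restarts: int
    best_start: np.ndarray
    non_identifiable: bool = False
    message: str = ""

    @property
    def negloglik(self) -> float:
        return -self.loglik

    def to_record(self, participant_id: str = "") -> dict:
        rec = {
            "participant_id": participant_id,
            "model_id": self.model_id,
            "loglik": self.loglik,
            "theta": self.rule.theta,
            "n_trials_used": self.n_trials_used,
            "converged": self.converged,
            "non_identifiable": self.non_identifiable,
        }
        rec.update(self.params.free_values())
        return rec


@dataclass
class GroupFit:
    """Per-participant fits plus group-level parameter summaries."""

    model_id: str
    fits: dict  # participant_id -> FitResult
    summary: "pd.DataFrame"  # noqa: F821 - imported lazily below
    correlations: "pd.DataFrame"  # noqa: F821
    failures: dict = field(default_factory=dict)


# --- likelihood -----------------------------------------------------------


class _TrialArrays:
    """Column arrays for the scorable (non-MISSING) trials of one participant."""

    __slots__ = ("ss_amount", "ss_delay", "ll_amount", "ll_delay", "chose_ll", "n")

    def __init__(self, trials: Sequence[ChoiceTrial]):
        scored = [t for t in trials if t.chosen in ("SS", "LL")]
        self.n = len(scored)
        self.ss_amount = np.array([t.ss.amount for t in scored])
        self.ss_delay = np.array([t.ss.delay for t in scored])
        self.ll_amount = np.array([t.ll.amount for t in scored])
        self.ll_delay = np.array([t.ll.delay for t in scored])
        self.chose_ll = np.array([t.chosen == "LL" for t in scored])


def _nll_arrays(arrays: _TrialArrays, params: DiscountParams, rule: ChoiceRule) -> float:
    m = params.model_id
    if m in ("HYP", "IMM_BIAS", "SS_BIAS"):
        d_ss = 1.0 / (1.0 + params.kappa * arrays.ss_delay)
        d_ll = 1.0 / (1.0 + params.kappa * arrays.ll_delay)
    elif m == "HYP2":
        d_ss = (1.0 + params.kappa * arrays.ss_delay) ** (-params.sigma)
        d_ll = (1.0 + params.kappa * arrays.ll_delay) ** (-params.sigma)
    else:
        d_ss = params.omega * params.delta1**arrays.ss_delay + (
            1.0 - params.omega
        ) * params.delta2**arrays.ss_delay
        d_ll = params.omega * params.delta1**arrays.ll_delay + (
            1.0 - params.omega
        ) * params.delta2**arrays.ll_delay
    if m == "SS_BIAS":
        b = params.bias
    elif m == "IMM_BIAS":
        b = np.where(arrays.ss_delay == 0, params.bias, 0.0)
    else:
        b = 0.0
    x = rule.theta * (d_ll * arrays.ll_amount - (d_ss * arrays.ss_amount + b))
    # -log P(observed): logaddexp form of the logistic, capped consistently
    # with the probability clipping in models.PROB_EPS.
    signed = np.where(arrays.chose_ll, -x, x)
    terms = np.minimum(np.logaddexp(0.0, signed), _NLL_CAP)
    return float(terms.sum())


def negloglik(
    trials: Sequence[ChoiceTrial],
    params: DiscountParams,
    rule: ChoiceRule,
) -> float:
    """Summed negative log-likelihood (nats) over the scorable trials."""
    arrays = _TrialArrays(trials)
    if arrays.n == 0:
        raise ValueError("no scorable trials (all responses MISSING)")
    return _nll_arrays(arrays, params, rule)


# --- parameter transforms -------------------------------------------------


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _pack(model_id: str, values: dict, theta: float, cfg: FitConfig) -> np.ndarray:
    if model_id == "HYP":
        x = [math.log(values["kappa"])]
    elif model_id == "HYP2":
        x = [math.log(values["kappa"]), math.log(values["sigma"])]
    elif model_id in ("IMM_BIAS", "SS_BIAS"):
        b = np.clip(values["bias"] / cfg.bias_bound, -0.999999, 0.999999)
        x = [math.log(values["kappa"]), float(np.arctanh(b)) * cfg.bias_bound]
    else:  # DUAL
        d2 = values["delta2"]
        u = values["delta1"] / d2
        x = [float(_logit(d2)), float(_logit(np.clip(u, 1e-9, 1 - 1e-9))), float(_logit(values["omega"]))]
    x.append(math.log(theta))
    return np.asarray(x, dtype=float)


def _unpack(model_id: str, x: np.ndarray, cfg: FitConfig):
    theta = float(np.exp(np.clip(x[-1], -30.0, 8.0)))
    if model_id == "HYP":
        params = DiscountParams.hyperbolic(float(np.exp(np.clip(x[0], -30.0, 8.0))))
    elif model_id == "HYP2":
        params = DiscountParams.hyperbolic2(
            float(np.exp(np.clip(x[0], -30.0, 8.0))),
            float(np.exp(np.clip(x[1], -10.0, 5.0))),
        )
    elif model_id in ("IMM_BIAS", "SS_BIAS"):
        bias = cfg.bias_bound * math.tanh(x[1] / cfg.bias_bound)
        params = DiscountParams(
            model_id,
            kappa=float(np.exp(np.clip(x[0], -30.0, 8.0))),
            bias=bias,
        )
    else:
        d2 = float(_logistic(np.atleast_1d(x[0]))[0])
        u = float(_logistic(np.atleast_1d(x[1]))[0])
        omega = float(_logistic(np.atleast_1d(x[2]))[0])
        d2 = min(max(d2, 1e-9), 1.0 - 1e-12)
        d1 = d2 * min(max(u, 1e-9), 1.0 - 1e-12)
        params = DiscountParams.dual(d1, d2, omega)
    return params, ChoiceRule(theta)


def _start_points(model_id: str, cfg: FitConfig) -> np.ndarray:
    """Latin-hypercube starting points in the transformed space."""
    if model_id == "HYP":
        ranges = [("log", cfg.kappa_range)]
    elif model_id == "HYP2":
        ranges = [("log", cfg.kappa_range), ("log", cfg.sigma_range)]
    elif model_id in ("IMM_BIAS", "SS_BIAS"):
        ranges = [("log", cfg.kappa_range), ("bias", cfg.bias_range)]
    else:
        ranges = [
            ("logit", cfg.delta_range),
            ("unit", (0.1, 0.9)),  # ratio delta1/delta2
            ("logit", cfg.omega_range),
        ]
    ranges.append(("log", cfg.theta_range))
    sampler = qmc.LatinHypercube(d=len(ranges), seed=cfg.seed)
    unit = sampler.random(n=cfg.n_restarts)
    cols = []
    for j, (kind, (lo, hi)) in enumerate(ranges):
        u = unit[:, j]
        if kind == "log":
            val = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
            cols.append(np.log(val))
        elif kind == "bias":
            b = lo + u * (hi - lo)
            b = np.clip(b / cfg.bias_bound, -0.999, 0.999)
            cols.append(np.arctanh(b) * cfg.bias_bound)
        elif kind == "logit":
            cols.append(_logit(lo + u * (hi - lo)))
        else:  # unit-interval parameter entered via logit
            cols.append(_logit(lo + u * (hi - lo)))
    return np.column_stack(cols)


def _objective_factory(model_id: str, arrays: _TrialArrays, cfg: FitConfig):
    """Specialized negative-log-likelihood closure over the transformed
    parameter vector; avoids per-evaluation container construction in the
    simplex search's inner loop."""
    ss_amount, ss_delay = arrays.ss_amount, arrays.ss_delay
    ll_amount, ll_delay = arrays.ll_amount, arrays.ll_delay
    sign = np.where(arrays.chose_ll, -1.0, 1.0)
    bound = cfg.bias_bound

    def _terms(x_val):
        terms = np.logaddexp(0.0, sign * x_val)
        np.minimum(terms, _NLL_CAP, out=terms)
        return float(terms.sum())

    if model_id in ("HYP", "SS_BIAS", "IMM_BIAS"):
        if model_id == "IMM_BIAS":
            bias_mask = (ss_delay == 0).astype(float)
        elif model_id == "SS_BIAS":
            bias_mask = 1.0
        else:
            bias_mask = 0.0

        has_bias = model_id != "HYP"

        def objective(x):
            kappa = math.exp(min(max(x[0], -30.0), 8.0))
            theta = math.exp(min(max(x[-1], -30.0), 8.0))
            b = bound * math.tanh(x[1] / bound) if has_bias else 0.0
            d_ss = 1.0 / (1.0 + kappa * ss_delay)
            d_ll = 1.0 / (1.0 + kappa * ll_delay)
            return _terms(theta * (ll_amount * d_ll - ss_amount * d_ss - b * bias_mask))

    elif model_id == "HYP2":

        def objective(x):
            kappa = math.exp(min(max(x[0], -30.0), 8.0))
            sigma = math.exp(min(max(x[1], -10.0), 5.0))
            theta = math.exp(min(max(x[-1], -30.0), 8.0))
            d_ss = (1.0 + kappa * ss_delay) ** (-sigma)
            d_ll = (1.0 + kappa * ll_delay) ** (-sigma)
            return _terms(theta * (ll_amount * d_ll - ss_amount * d_ss))

    else:  # DUAL

        def objective(x):
            d2 = 1.0 / (1.0 + math.exp(-min(max(x[0], -35.0), 35.0)))
            u = 1.0 / (1.0 + math.exp(-min(max(x[1], -35.0), 35.0)))
            omega = 1.0 / (1.0 + math.exp(-min(max(x[2], -35.0), 35.0)))
            theta = math.exp(min(max(x[3], -30.0), 8.0))
            d1 = d2 * u
            d_ss = omega * d1**ss_delay + (1.0 - omega) * d2**ss_delay
            d_ll = omega * d1**ll_delay + (1.0 - omega) * d2**ll_delay
            return _terms(theta * (ll_amount * d_ll - ss_amount * d_ss))

    return objective


# --- fitting --------------------------------------------------------------


def fit_participant(
    trials: Sequence[ChoiceTrial],
    model_id: str,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one model to one participant's choices by multistart MLE.

    Deterministic given ``config.seed``. Participants whose scorable choices
    are all-SS or all-LL are still fit but flagged non-identifiable (the
    likelihood is unbounded along theta and parameters sit at a bound).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    cfg = config or FitConfig()
    arrays = _TrialArrays(trials)
    if arrays.n == 0:
        raise ValueError("no scorable trials (all responses MISSING)")
    if arrays.n < cfg.min_trials:
        raise ValueError(
            f"only {arrays.n} scorable trials; at least {cfg.min_trials} required"
        )
    n_ll = int(arrays.chose_ll.sum())
    degenerate = n_ll == 0 or n_ll == arrays.n
    objective = _objective_factory(model_id, arrays, cfg)

    starts = _start_points(model_id, cfg)
    best = None
    best_x = None
    best_start = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": cfg.ftol,
                "xatol": 1e-6,
                "maxiter": cfg.max_iter,
                "maxfev": 4 * cfg.max_iter,
            },
        )
        if best is None or res.fun < best - 1e-12:
            best, best_x, best_start = res.fun, res.x, x0
            any_converged = bool(res.success)
        elif abs(res.fun - best) <= 1e-12 and res.success:
            any_converged = True
    params, rule = _unpack(model_id, best_x, cfg)
    converged = any_converged and not degenerate
    if degenerate:
        log.warning(
            "degenerate choice data (all-%s): %s fit flagged non-identifiable",
            "LL" if n_ll == arrays.n else "SS",
            model_id,
        )
    return FitResult(
        model_id=model_id,
        params=params,
        rule=rule,
        loglik=-best,
        n_trials_used=arrays.n,
        converged=converged,
        n_restarts=cfg.n_restarts,
        best_start=best_start,
        non_identifiable=degenerate,
        message="degenerate choice data" if degenerate else "",
    )


def fit_group(
    trials_by_participant: dict,
    model_id: str,
    config: Optional[FitConfig] = None,
) -> GroupFit:
    """Fit a model to every participant and summarise the parameters.

    The summary reports the mean and the standard error of the mean
    (SD / sqrt(N)) of every fitted parameter, plus pairwise Pearson
    correlations between parameters across participants. Participants whose
    individual fit fails are recorded under ``failures`` and excluded.
    """
    import pandas as pd

    if len(trials_by_participant) < 2:
        raise ValueError("fit_group requires at least 2 participants")
    cfg = config or FitConfig()
    fits: dict = {}
    failures: dict = {}
    for i, (pid, trials) in enumerate(trials_by_participant.items()):
        try:
            fits[pid] = fit_participant(
                trials, model_id, replace(cfg, seed=cfg.seed + 7919 * i)
            )
        except ValueError as exc:
            failures[pid] = str(exc)
    if failures:
        log.warning("%d participant fit(s) failed and were excluded", len(failures))
    if len(fits) < 2:
        raise ValueError("fewer than 2 successful fits; cannot summarise")
    records = pd.DataFrame(
        [f.to_record(pid) for pid, f in fits.items()]
    ).set_index("participant_id")
    param_cols = [
        c
        for c in records.columns
        if c not in ("model_id", "converged", "non_identifiable", "n_trials_used", "loglik")
    ]
    values = records[param_cols].astype(float)
    n = len(values)
    summary = pd.DataFrame(
        {
            "mean": values.mean(),
            "sd": values.std(ddof=1),
            "se": values.std(ddof=1) / math.sqrt(n),
            "n": n,
        }
    )
    correlations = values.corr()
    return GroupFit(
        model_id=model_id,
        fits=fits,
        summary=summary,
        correlations=correlations,
        failures=failures,
    )
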