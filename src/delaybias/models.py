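"""Discounted-utility models of intertemporal choice with a logistic choice rule.

Five models of how a delayed monetary amount is devalued, all of the form
``U = D(t) * A`` where ``A`` is the objective amount and ``D(t)`` a discount
factor in (0, 1]:

``HYP``
    Classic one-parameter hyperbolic discounting, ``D = 1 / (1 + kappa * t)``.
``HYP2``
    Two-parameter hyperbolic, ``D = 1 / (1 + kappa * t)**sigma``; ``sigma``
    captures differential sensitivity to short versus long delays.
``DUAL``
    Dual-system mixture of two exponential discounters,
    ``D = omega * delta1**t + (1 - omega) * delta2**t`` with
    ``delta1 < delta2`` (one system is strictly more impatient).
``IMM_BIAS``
    Hyperbolic valuation plus a response bias added to the smaller-sooner
    option's value, active only when that option is available today.
``SS_BIAS``
    Hyperbolic valuation plus a response bias toward the smaller-sooner
    option on every trial, regardless of its delay.

Choices follow a logistic (softmax) rule on the subjective-value difference:
``P(LL) = 1 / (1 + exp(-theta * (V_LL - (V_SS + bias))))`` where ``theta``
is choice consistency (inverse temperature; theta = 0 is random choice) and
``bias`` is the model-dependent effective offset (zero for the non-bias
models). A positive bias shifts choice toward the smaller-sooner option
independently of valuation.

Time is measured in days throughout; delay 0 means "today". Amounts are in
euros, so the bias parameter is expressed in euros of subjective value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MODEL_IDS",
    "N_PARAMS",
    "PROB_EPS",
    "Prospect",
    "DiscountParams",
    "ChoiceRule",
    "discount_factor",
    "subjective_value",
    "effective_bias",
    "prob_choose_ll",
    "prob_choose_ss",
]

MODEL_IDS = ("HYP", "HYP2", "DUAL", "IMM_BIAS", "SS_BIAS")

#: Free parameters per model, including the inverse temperature theta.
N_PARAMS = {"HYP": 2, "HYP2": 3, "DUAL": 4, "IMM_BIAS": 3, "SS_BIAS": 3}

#: Probabilities returned by the choice rule are clipped to
#: [PROB_EPS, 1 - PROB_EPS] so that downstream log-likelihoods stay finite.
PROB_EPS = 1e-12

_MODEL_FIELDS = {
    "HYP": ("kappa",),
    "HYP2": ("kappa", "sigma"),
    "DUAL": ("delta1", "delta2", "omega"),
    "IMM_BIAS": ("kappa", "bias"),
    "SS_BIAS": ("kappa", "bias"),
}


@dataclass(frozen=True)
class Prospect:
    """A monetary amount (euros, > 0) available after a delay (days, >= 0)."""

    amount: float
    delay: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.amount) and self.amount > 0):
            raise ValueError(f"amount must be finite and > 0, got {self.amount}")
        if not (math.isfinite(self.delay) and self.delay >= 0):
            raise ValueError(f"delay must be finite and >= 0, got {self.delay}")

    @property
    def immediate(self) -> bool:
        return self.delay == 0


@dataclass(frozen=True)
class ChoiceRule:
    """Logistic choice rule with inverse temperature ``theta`` (1/euro)."""

    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and self.theta >= 0):
            raise ValueError(f"theta must be finite and >= 0, got {self.theta}")


@dataclass(frozen=True)
class DiscountParams:
    """Parameter set for one of the five discounting models.

    Only the fields belonging to ``model_id`` may be set; validation raises a
    ``ValueError`` naming the offending parameter.
    """

    model_id: str
    kappa: Optional[float] = None
    sigma: Optional[float] = None
    delta1: Optional[float] = None
    delta2: Optional[float] = None
    omega: Optional[float] = None
    bias: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        required = _MODEL_FIELDS[self.model_id]
        for name in ("kappa", "sigma", "delta1", "delta2", "omega", "bias"):
            value = getattr(self, name)
            if name in required:
                if value is None:
                    raise ValueError(f"{self.model_id} requires parameter {name}")
                if not math.isfinite(value):
                    raise ValueError(f"{name} must be finite, got {value}")
            elif value is not None:
                raise ValueError(f"{self.model_id} does not use parameter {name}")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        for name in ("delta1", "delta2"):
            value = getattr(self, name)
            if value is not None and not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.omega is not None and not (0 <= self.omega <= 1):
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if self.model_id == "DUAL" and not (self.delta1 < self.delta2):
            raise ValueError(
                f"DUAL requires delta1 < delta2, got {self.delta1} >= {self.delta2}"
            )

    # Convenience constructors -------------------------------------------------

    @staticmethod
    def hyperbolic(kappa: float) -> "DiscountParams":
        return DiscountParams("HYP", kappa=kappa)

    @staticmethod
    def hyperbolic2(kappa: float, sigma: float) -> "DiscountParams":
        return DiscountParams("HYP2", kappa=kappa, sigma=sigma)

    @staticmethod
    def dual(delta1: float, delta2: float, omega: float) -> "DiscountParams":
        return DiscountParams("DUAL", delta1=delta1, delta2=delta2, omega=omega)

    @staticmethod
    def ss_bias(kappa: float, bias: float) -> "DiscountParams":
        return DiscountParams("SS_BIAS", kappa=kappa, bias=bias)

    @staticmethod
    def imm_bias(kappa: float, bias: float) -> "DiscountParams":
        return DiscountParams("IMM_BIAS", kappa=kappa, bias=bias)

    def free_values(self) -> dict:
        """The free discount parameters as a name -> value mapping."""
        return {name: getattr(self, name) for name in _MODEL_FIELDS[self.model_id]}


def discount_factor(params: DiscountParams, delay):
    """Discount factor D(t) in (0, 1] for a delay in days.

    Accepts a scalar or array delay; D(0) = 1 for every model and D is
    non-increasing in delay.
    """
    t = np.asarray(delay, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("delay must be finite and >= 0")
    m = params.model_id
    if m in ("HYP", "IMM_BIAS", "SS_BIAS"):
        d = 1.0 / (1.0 + params.kappa * t)
    elif m == "HYP2":
        d = (1.0 + params.kappa * t) ** (-params.sigma)
    else:  # DUAL
        d = params.omega * params.delta1**t + (1.0 - params.omega) * params.delta2**t
    return d if d.ndim else float(d)


def subjective_value(prospect: Prospect, params: DiscountParams) -> float:
    """Subjective utility U = D(delay) * amount, in euros."""
    return float(discount_factor(params, prospect.delay)) * prospect.amount


def effective_bias(params: DiscountParams, ss_delay: float) -> float:
    """The bias added to the SS option's value on a trial.

    SS_BIAS applies its bias on every trial; IMM_BIAS only when the SS option
    is available today (delay exactly 0); the pure valuation models have none.
    """
    if params.model_id == "SS_BIAS":
        return params.bias
    if params.model_id == "IMM_BIAS":
        return params.bias if ss_delay == 0 else 0.0
    return 0.0


def _logistic(x):
    # Numerically stable logistic; never overflows.
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _pll(ss_amount, ss_delay, ll_amount, ll_delay, params, rule):
    """Vectorized P(choose LL); arrays in, clipped array out."""
    d_ss = np.asarray(discount_factor(params, ss_delay), dtype=float)
    d_ll = np.asarray(discount_factor(params, ll_delay), dtype=float)
    v_ss = d_ss * np.asarray(ss_amount, dtype=float)
    v_ll = d_ll * np.asarray(ll_amount, dtype=float)
    if params.model_id == "SS_BIAS":
        b = params.bias
    elif params.model_id == "IMM_BIAS":
        b = np.where(np.asarray(ss_delay) == 0, params.bias, 0.0)
    else:
        b = 0.0
    x = rule.theta * (v_ll - (v_ss + b))
    return np.clip(_logistic(np.atleast_1d(x)), PROB_EPS, 1.0 - PROB_EPS)


def prob_choose_ll(trial, params: DiscountParams, rule: ChoiceRule) -> float:
    """Probability of choosing the larger-later option on one trial."""
    p = _pll(
        trial.ss.amount, trial.ss.delay, trial.ll.amount, trial.ll.delay, params, rule
    )
    return float(p[0])


def prob_choose_ss(trial, params: DiscountParams, rule: ChoiceRule) -> float:
    """Probability of choosing the smaller-sooner option: 1 - P(LL)."""
    v_ss = subjective_value(trial.ss, params)
    v_ll = subjective_value(trial.ll, params)
    b = effective_bias(params, trial.ss.delay)
    x = rule.theta * (v_ll - (v_ss + b))
    p = _logistic(np.atleast_1d(-x))
    return float(np.clip(p, PROB_EPS, 1.0 - PROB_EPS)[0])
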