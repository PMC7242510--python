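"""Adaptive staircase titration and tailored scanner-set generation.

The pre-scanner task presents 60 binary choices between a fixed
smaller-sooner option (10 euros today) and a larger-later amount at a delay
drawn from 15-60 days. The LL amount is titrated toward the participant's
indifference point by per-delay-bin bisection: the 15-60 day range is split
into four bins with 15 trials each (interleaved in random order); choosing
LL lowers that bin's upper amount bound, choosing SS raises its lower bound,
and the next amount proposed in the bin is the bound midpoint. After 60
trials the hyperbolic model is fit to the staircase choices, and the
resulting discount-rate estimate kappa_hat is used to build an individually
tailored 64-trial scanner set whose model-predicted value differences sit in
a narrow band around indifference - the design goal being a roughly 50/50
split of SS and LL choices. Half of the scanner trials offer the SS option
"today" (NOW condition), half place both options in the future (LATER).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .models import ChoiceRule, DiscountParams, Prospect, discount_factor, prob_choose_ll
from .trials import ChoiceTrial
from .fitting import FitConfig, FitResult, fit_participant

__all__ = [
    "StaircaseConfig",
    "ScannerConfig",
    "StaircaseState",
    "StaircaseRun",
    "staircase_next",
    "simulate_agent_choice",
    "run_staircase",
    "generate_scanner_set",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StaircaseConfig:
    n_trials: int = 60
    ss_amount: float = 10.0
    delay_range: Tuple[int, int] = (15, 60)
    n_bins: int = 4
    amount_cap: float = 300.0
    resolution: float = 0.01


@dataclass(frozen=True)
class ScannerConfig:
    """Construction rules for the tailored 64-trial scanner design.

    SS amounts are drawn log-uniformly over ``ss_amount_range`` (wide
    multiplicative spread separates the additive response bias from the
    multiplicative discount), LL delays come from the short/long extremes of
    ``ll_delay_choices`` (maximal delay contrast pins the discount rate),
    and the targeted subjective-value difference V_LL - V_SS under the
    fitted hyperbolic model is uniform on ``+/- value_band_eur`` euros - a
    symmetric band around indifference whose width keeps predicted choice
    probabilities inside the informative range of the logistic rule at
    typical choice consistency.
    """

    n_trials: int = 64
    ss_amount_range: Tuple[float, float] = (2.5, 80.0)
    ss_later_delay_range: Tuple[int, int] = (2, 15)
    ll_delay_choices: Tuple[int, ...] = (15, 60)
    ll_delay_gap_choices: Tuple[int, ...] = (13, 45)
    value_band_eur: float = 10.0
    round_step: float = 0.5
    amount_cap: float = 300.0


@dataclass
class _BinState:
    lo: float
    hi: float
    delays: List[int]  # integer days available to this bin
    converged: bool = False


@dataclass
class StaircaseState:
    """Mutable state of a staircase run; one bisection bracket per delay bin."""

    config: StaircaseConfig
    bins: List[_BinState]
    schedule: List[int]  # bin index per trial
    delays: List[int]  # LL delay per trial (days)
    trial_index: int = 0
    history: List[ChoiceTrial] = field(default_factory=list)
    _pending: Optional[Tuple[int, ChoiceTrial]] = None

    @classmethod
    def initialize(cls, seed: int, config: Optional[StaircaseConfig] = None):
        cfg = config or StaircaseConfig()
        rng = np.random.default_rng(seed)
        lo_day, hi_day = cfg.delay_range
        all_days = np.arange(lo_day, hi_day + 1)
        day_bins = np.array_split(all_days, cfg.n_bins)
        per_bin = cfg.n_trials // cfg.n_bins
        bins = [
            _BinState(lo=cfg.ss_amount, hi=cfg.amount_cap, delays=list(map(int, days)))
            for days in day_bins
        ]
        schedule = np.repeat(np.arange(cfg.n_bins), per_bin)
        rng.shuffle(schedule)
        delays = [int(rng.choice(bins[b].delays)) for b in schedule]
        return cls(config=cfg, bins=bins, schedule=list(map(int, schedule)), delays=delays)

    @property
    def done(self) -> bool:
        return self.trial_index >= self.config.n_trials

    def propose(self) -> ChoiceTrial:
        """The next trial to administer (LL amount at the bracket midpoint)."""
        if self.done:
            raise ValueError("staircase finished")
        b = self.bins[self.schedule[self.trial_index]]
        amount = (b.lo + b.hi) / 2.0
        if b.hi - b.lo < self.config.resolution:
            b.converged = True
        trial = ChoiceTrial(
            Prospect(self.config.ss_amount, 0.0),
            Prospect(max(amount, self.config.ss_amount + self.config.resolution),
                     float(self.delays[self.trial_index])),
        )
        self._pending = (self.schedule[self.trial_index], trial)
        return trial

    def record(self, response: str) -> None:
        """Record the response to the pending trial and update the bracket.

        Choosing LL means the offered amount was at or above indifference, so
        the upper bound comes down; choosing SS raises the lower bound.
        """
        if self._pending is None:
            raise ValueError("no pending trial; call propose() first")
        bin_idx, trial = self._pending
        b = self.bins[bin_idx]
        if response == "LL":
            b.hi = trial.ll.amount
        elif response == "SS":
            b.lo = trial.ll.amount
        elif response != "MISSING":
            raise ValueError(f"response must be SS, LL or MISSING, got {response!r}")
        b.lo, b.hi = min(b.lo, b.hi), max(b.lo, b.hi)
        self.history.append(trial.with_choice(response))
        self.trial_index += 1
        self._pending = None

    def implied_indifference(self) -> dict:
        """Bin-center delay -> midpoint of the final amount bracket."""
        return {
            float(np.mean(b.delays)): (b.lo + b.hi) / 2.0 for b in self.bins
        }


def staircase_next(state: StaircaseState, last_response: Optional[str]) -> ChoiceTrial:
    """Functional driver: record ``last_response`` (if any) and propose the
    next trial."""
    if last_response is not None:
        state.record(last_response)
    return state.propose()


def simulate_agent_choice(
    trial: ChoiceTrial,
    params: DiscountParams,
    rule: ChoiceRule,
    rng: np.random.Generator,
) -> str:
    """Bernoulli response of a model agent to one trial."""
    p_ll = prob_choose_ll(trial, params, rule)
    return "LL" if rng.random() < p_ll else "SS"


@dataclass
class StaircaseRun:
    trials: List[ChoiceTrial]
    kappa_hat: float
    fit: FitResult
    indifference: dict


def run_staircase(
    agent_params: DiscountParams,
    rule: ChoiceRule,
    seed: int,
    config: Optional[StaircaseConfig] = None,
    fit_config: Optional[FitConfig] = None,
    agent: Optional[Callable[[ChoiceTrial], str]] = None,
) -> StaircaseRun:
    """Simulate the 60-trial staircase and fit the hyperbolic model to it.

    ``agent`` may override the default Bernoulli model agent (it receives the
    proposed trial and returns "SS"/"LL"). Deterministic given ``seed``.
    """
    state = StaircaseState.initialize(seed, config)
    rng = np.random.default_rng(seed + 1)
    while not state.done:
        trial = state.propose()
        if agent is not None:
            resp = agent(trial)
        else:
            resp = simulate_agent_choice(trial, agent_params, rule, rng)
        state.record(resp)
    fcfg = fit_config or FitConfig()
    fit = fit_participant(state.history, "HYP", fcfg)
    return StaircaseRun(
        trials=state.history,
        kappa_hat=fit.params.kappa,
        fit=fit,
        indifference=state.implied_indifference(),
    )


def _round_step(x, step):
    return np.maximum(np.round(np.asarray(x) / step) * step, step)


def generate_scanner_set(
    kappa_hat: float,
    seed: int,
    config: Optional[ScannerConfig] = None,
) -> List[ChoiceTrial]:
    """Build the tailored 64-trial scanner design from a fitted kappa.

    Exactly half the trials are NOW (SS available today), half LATER. For
    each trial the LL amount is solved so that the hyperbolic
    model-predicted value difference V_LL - V_SS lies at a uniformly drawn
    point inside ``+/- value_band_eur`` euros; amounts are rounded to
    ``round_step`` euros. As kappa_hat -> 0 the solved LL amounts approach
    the SS amount and the generator enforces a minimal amount gap instead.
    """
    if not (kappa_hat > 0 and np.isfinite(kappa_hat)):
        raise ValueError(f"kappa_hat must be > 0, got {kappa_hat}")
    cfg = config or ScannerConfig()
    rng = np.random.default_rng(seed)
    n_now = cfg.n_trials // 2
    conditions = np.array(["NOW"] * n_now + ["LATER"] * (cfg.n_trials - n_now))
    rng.shuffle(conditions)
    hyp = DiscountParams.hyperbolic(kappa_hat)
    lo_amt, hi_amt = cfg.ss_amount_range
    trials: List[ChoiceTrial] = []
    clipped = 0
    for cond in conditions:
        if cond == "NOW":
            ss_delay = 0
            ll_delay = int(rng.choice(cfg.ll_delay_choices))
        else:
            ss_delay = int(
                rng.integers(cfg.ss_later_delay_range[0], cfg.ss_later_delay_range[1] + 1)
            )
            ll_delay = ss_delay + int(rng.choice(cfg.ll_delay_gap_choices))
        ss_amount = float(
            _round_step(
                np.exp(rng.uniform(np.log(lo_amt), np.log(hi_amt))), cfg.round_step
            )
        )
        v_ss = ss_amount * float(discount_factor(hyp, ss_delay))
        v_target = v_ss + rng.uniform(-cfg.value_band_eur, cfg.value_band_eur)
        ll_amount = float(
            _round_step(v_target / float(discount_factor(hyp, ll_delay)), cfg.round_step)
        )
        lo = ss_amount + cfg.round_step
        if ll_amount > cfg.amount_cap:
            clipped += 1
        # the lower clip is routine: a patient kappa_hat needs almost no LL
        # premium, so the design simply shrinks the amount gap to the
        # rounding step
        ll_amount = float(np.clip(ll_amount, lo, cfg.amount_cap))
        trials.append(
            ChoiceTrial(
                Prospect(ss_amount, float(ss_delay)),
                Prospect(ll_amount, float(ll_delay)),
            )
        )
    if clipped:
        log.warning(
            "scanner set: %d/%d LL amounts saturated at the %.0f-euro cap "
            "(kappa_hat=%.4g too extreme for the targeted value band)",
            clipped,
            cfg.n_trials,
            cfg.amount_cap,
            kappa_hat,
        )
    return trials
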