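"""Maximum-likelihood fitting: likelihood correctness, determinism, recovery."""

import math
import random

import numpy as np
import pytest

from delaybias.models import (
    ChoiceRule,
    DiscountParams,
    Prospect,
    prob_choose_ll,
    prob_choose_ss,
)
from delaybias.trials import ChoiceTrial
from delaybias.fitting import FitConfig, fit_group, fit_participant, negloglik
from delaybias.staircase import generate_scanner_set, simulate_agent_choice


def _random_trials(rng, n=20, with_choices=True):
    trials = []
    for _ in range(n):
        ss_amount = rng.uniform(2, 40)
        ss_delay = float(rng.integers(0, 16))
        trials.append(
            ChoiceTrial(
                Prospect(ss_amount, ss_delay),
                Prospect(ss_amount + rng.uniform(0.5, 100), ss_delay + rng.uniform(1, 60)),
                rng.choice(["SS", "LL"]) if with_choices else None,
            )
        )
    return trials


def _brute_force_nll(trials, params, rule):
    total = 0.0
    for t in trials:
        if t.chosen == "LL":
            total -= math.log(prob_choose_ll(t, params, rule))
        elif t.chosen == "SS":
            total -= math.log(prob_choose_ss(t, params, rule))
    return total


def test_negloglik_matches_brute_force_per_trial_sum():
    rng = np.random.default_rng(11)
    for _ in range(20):
        trials = _random_trials(rng)
        params = DiscountParams.ss_bias(rng.uniform(0.001, 0.5), rng.uniform(-30, 30))
        rule = ChoiceRule(rng.uniform(0.01, 1.0))
        assert negloglik(trials, params, rule) == pytest.approx(
            _brute_force_nll(trials, params, rule), abs=1e-10
        )


def test_negloglik_noise_only_model_is_n_log_two():
    rng = np.random.default_rng(0)
    trials = _random_trials(rng, n=64)
    nll = negloglik(trials, DiscountParams.hyperbolic(0.08), ChoiceRule(0.0))
    assert nll == pytest.approx(64 * math.log(2), abs=1e-12)


def test_missing_trials_contribute_nothing():
    rng = np.random.default_rng(3)
    trials = _random_trials(rng, n=30)
    with_missing = trials + [
        ChoiceTrial(Prospect(10, 0), Prospect(20, 30), "MISSING")
    ]
    params = DiscountParams.hyperbolic(0.1)
    rule = ChoiceRule(0.3)
    assert negloglik(with_missing, params, rule) == pytest.approx(
        negloglik(trials, params, rule)
    )
    all_missing = [t.with_choice("MISSING") for t in trials]
    with pytest.raises(ValueError, match="scorable"):
        negloglik(all_missing, params, rule)


@pytest.fixture(scope="module")
def simulated_participant():
    """64 tailored trials from a response-bias agent (kappa .08, bias 14.29)."""
    params = DiscountParams.ss_bias(0.08, 14.29)
    rule = ChoiceRule(0.2)
    design = generate_scanner_set(0.23, seed=5)
    rng = np.random.default_rng(6)
    return [t.with_choice(simulate_agent_choice(t, params, rule, rng)) for t in design]


def test_fit_is_deterministic_given_seed(simulated_participant):
    f1 = fit_participant(simulated_participant, "SS_BIAS", FitConfig(seed=4))
    f2 = fit_participant(simulated_participant, "SS_BIAS", FitConfig(seed=4))
    assert f1.loglik == f2.loglik
    assert f1.params == f2.params
    assert f1.rule == f2.rule


def test_fit_is_invariant_to_trial_order(simulated_participant):
    shuffled = list(simulated_participant)
    random.Random(9).shuffle(shuffled)
    f1 = fit_participant(simulated_participant, "SS_BIAS", FitConfig(seed=4))
    f2 = fit_participant(shuffled, "SS_BIAS", FitConfig(seed=4))
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-12)
    assert f1.params.bias == pytest.approx(f2.params.bias, abs=1e-9)


def test_fit_agrees_across_seeds_on_well_conditioned_data(simulated_participant):
    f1 = fit_participant(simulated_participant, "SS_BIAS", FitConfig(seed=1))
    f2 = fit_participant(simulated_participant, "SS_BIAS", FitConfig(seed=2))
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


def test_degenerate_all_one_sided_choices_flagged(simulated_participant):
    all_ll = [t.with_choice("LL") for t in simulated_participant]
    fit = fit_participant(all_ll, "HYP", FitConfig(seed=0))
    assert fit.non_identifiable
    assert not fit.converged


def test_too_few_trials_rejected(simulated_participant):
    with pytest.raises(ValueError, match="at least"):
        fit_participant(simulated_participant[:5], "HYP", FitConfig(min_trials=20))


def test_fit_group_identical_participants_have_zero_se(simulated_participant):
    trials = {"a": simulated_participant, "b": simulated_participant}
    cfg = FitConfig(seed=0, n_restarts=6)
    gf = fit_group(trials, "SS_BIAS", cfg)
    # per-participant seeds differ, but identical data must give identical
    # optima, hence zero SE of every parameter mean
    assert (gf.summary["se"].abs() < 1e-3).all()
    with pytest.raises(ValueError, match="at least 2"):
        fit_group({"a": simulated_participant}, "SS_BIAS", cfg)


def test_bias_parameter_recovery_correlates_with_truth():
    """Across agents spanning the plausible bias range, recovered bias must
    track the generating bias (rank-preserving recovery)."""
    rng = np.random.default_rng(21)
    true_bias = np.linspace(-20, 40, 12)
    recovered = []
    for i, b in enumerate(true_bias):
        params = DiscountParams.ss_bias(0.08, float(b))
        rule = ChoiceRule(0.2)
        design = generate_scanner_set(0.23, seed=100 + i)
        trials = [
            t.with_choice(simulate_agent_choice(t, params, rule, rng)) for t in design
        ]
        fit = fit_participant(trials, "SS_BIAS", FitConfig(seed=i, n_restarts=6))
        recovered.append(fit.params.bias)
    r = np.corrcoef(true_bias, recovered)[0, 1]
    assert r > 0.8
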