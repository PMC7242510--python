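"""Adaptive staircase titration and scanner-set generation."""

import numpy as np
import pytest

from delaybias.models import ChoiceRule, DiscountParams
from delaybias.fitting import FitConfig
from delaybias.staircase import (
    ScannerConfig,
    StaircaseState,
    generate_scanner_set,
    run_staircase,
    simulate_agent_choice,
    staircase_next,
)


def _run_fixed_policy(seed, response):
    state = StaircaseState.initialize(seed)
    amounts_by_bin = {i: [] for i in range(len(state.bins))}
    while not state.done:
        b = state.schedule[state.trial_index]
        trial = state.propose()
        amounts_by_bin[b].append(trial.ll.amount)
        state.record(response)
    return state, amounts_by_bin


def test_always_ss_drives_amounts_up_always_ll_down():
    _, up = _run_fixed_policy(0, "SS")
    for amounts in up.values():
        assert all(b >= a for a, b in zip(amounts, amounts[1:]))
    state, down = _run_fixed_policy(0, "LL")
    for amounts in down.values():
        assert all(b <= a for a, b in zip(amounts, amounts[1:]))
    # all-LL titration heads toward the 10-euro SS amount
    assert all(v < 12 for v in state.implied_indifference().values())


def test_bisection_brackets_stay_ordered_and_shrink():
    params = DiscountParams.hyperbolic(0.05)
    rule = ChoiceRule(0.5)
    state = StaircaseState.initialize(3)
    rng = np.random.default_rng(4)
    widths = {i: [b.hi - b.lo] for i, b in enumerate(state.bins)}
    trial = state.propose()
    while True:
        b_idx = state.schedule[state.trial_index]
        response = simulate_agent_choice(trial, params, rule, rng)
        state.record(response)
        widths[b_idx].append(state.bins[b_idx].hi - state.bins[b_idx].lo)
        if state.done:
            break
        trial = staircase_next(state, None)
    for i, b in enumerate(state.bins):
        assert b.lo <= b.hi
        w = widths[i]
        assert all(w2 <= w1 + 1e-9 for w1, w2 in zip(w, w[1:]))


def test_same_seed_reproduces_trial_log_exactly():
    params = DiscountParams.hyperbolic(0.08)
    rule = ChoiceRule(2.0)
    r1 = run_staircase(params, rule, seed=7, fit_config=FitConfig(n_restarts=4))
    r2 = run_staircase(params, rule, seed=7, fit_config=FitConfig(n_restarts=4))
    assert r1.trials == r2.trials
    assert r1.kappa_hat == r2.kappa_hat


@pytest.mark.parametrize("kappa", [0.02, 0.08])
def test_noise_free_staircase_converges_to_analytic_indifference(kappa):
    """A deterministic hyperbolic agent's bracket midpoints approach the
    closed-form indifference amount 10 * (1 + kappa * d) per delay bin."""
    params = DiscountParams.hyperbolic(kappa)
    rule = ChoiceRule(1e7)
    run = run_staircase(params, rule, seed=11, fit_config=FitConfig(n_restarts=4))
    for d, amount in run.indifference.items():
        analytic = 10.0 * (1 + kappa * d)
        assert amount == pytest.approx(analytic, rel=0.15)
    assert run.kappa_hat == pytest.approx(kappa, rel=0.10)


def test_degenerate_agent_flagged():
    # an agent that always takes the larger-later option
    params = DiscountParams.hyperbolic(1e-4)
    rule = ChoiceRule(1e7)
    run = run_staircase(
        params, rule, seed=2, agent=lambda t: "LL", fit_config=FitConfig(n_restarts=3)
    )
    assert run.fit.non_identifiable


def test_scanner_design_invariants():
    design = generate_scanner_set(0.23, seed=13)
    assert len(design) == 64
    conditions = [t.condition for t in design]
    assert conditions.count("NOW") == 32
    assert conditions.count("LATER") == 32
    for t in design:
        assert t.ss.amount < t.ll.amount
        assert t.ss.delay < t.ll.delay
        assert t.chosen is None
    assert design == generate_scanner_set(0.23, seed=13)
    assert design != generate_scanner_set(0.23, seed=14)
    with pytest.raises(ValueError):
        generate_scanner_set(0.0, seed=1)


def test_scanner_design_shrinks_gaps_for_patient_agents():
    """As kappa_hat -> 0 the LL premium needed for indifference vanishes,
    so generated amount gaps collapse toward the rounding step."""
    patient = generate_scanner_set(1e-6, seed=5)
    gaps = np.array([t.ll.amount - t.ss.amount for t in patient])
    impatient = generate_scanner_set(0.3, seed=5)
    gaps_imp = np.array([t.ll.amount - t.ss.amount for t in impatient])
    assert np.median(gaps) < np.median(gaps_imp)
    assert (gaps >= 0.5 - 1e-12).all()


def test_closed_loop_choice_split_near_even():
    """Staircase -> tailored design -> same agent: SS share lands in the
    design's target band for a moderately noisy agent."""
    params = DiscountParams.ss_bias(0.08, 14.29)
    rule = ChoiceRule(0.2)
    fractions = []
    for seed in range(5):
        run = run_staircase(params, rule, seed=100 + seed,
                            fit_config=FitConfig(n_restarts=4))
        design = generate_scanner_set(run.kappa_hat, seed=200 + seed)
        rng = np.random.default_rng(300 + seed)
        choices = [simulate_agent_choice(t, params, rule, rng) for t in design]
        fractions.append(np.mean([c == "SS" for c in choices]))
    assert 0.35 <= np.mean(fractions) <= 0.65
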