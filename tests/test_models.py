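"""Discount functions, subjective values and the logistic choice rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delaybias.models import (
    ChoiceRule,
    DiscountParams,
    Prospect,
    discount_factor,
    effective_bias,
    prob_choose_ll,
    prob_choose_ss,
    subjective_value,
)
from delaybias.trials import ChoiceTrial

DELAY_GRID = np.arange(0.0, 366.0)

ALL_PARAMS = [
    DiscountParams.hyperbolic(0.08),
    DiscountParams.hyperbolic2(0.08, 0.7),
    DiscountParams.dual(0.9, 0.97, 0.4),
    DiscountParams.imm_bias(0.08, 14.29),
    DiscountParams.ss_bias(0.08, 14.29),
]


@pytest.mark.parametrize("params", ALL_PARAMS, ids=lambda p: p.model_id)
def test_discount_factor_is_one_today_and_non_increasing(params):
    d = discount_factor(params, DELAY_GRID)
    assert d[0] == pytest.approx(1.0)
    assert np.all(np.diff(d) <= 1e-15)
    assert np.all((d > 0) & (d <= 1))


@pytest.mark.parametrize(
    "params, delay, expected",
    [
        (DiscountParams.hyperbolic(0.08), 0.0, 1.0),
        # 1 / (1 + 0.08 * 12.5) = 0.5
        (DiscountParams.hyperbolic(0.08), 12.5, 0.5),
        # omega = 1 reduces the dual-system mixture to delta1 ** tau
        (DiscountParams.dual(0.9, 0.95, 1.0), 2.0, 0.81),
    ],
)
def test_discount_factor_values(params, delay, expected):
    assert discount_factor(params, delay) == pytest.approx(expected, abs=1e-12)


def test_subjective_value_examples():
    assert subjective_value(
        Prospect(10, 0), DiscountParams.hyperbolic(0.3)
    ) == pytest.approx(10.0)
    assert subjective_value(
        Prospect(20, 12.5), DiscountParams.hyperbolic(0.08)
    ) == pytest.approx(10.0)


def test_reduction_identities_hold_to_machine_precision():
    """HYP2(sigma=1) == HYP; DUAL(omega=1/0) == pure exponentials."""
    hyp = discount_factor(DiscountParams.hyperbolic(0.08), DELAY_GRID)
    hyp2 = discount_factor(DiscountParams.hyperbolic2(0.08, 1.0), DELAY_GRID)
    np.testing.assert_allclose(hyp2, hyp, rtol=0, atol=1e-15)

    dual1 = discount_factor(DiscountParams.dual(0.9, 0.95, 1.0), DELAY_GRID)
    np.testing.assert_allclose(dual1, 0.9**DELAY_GRID, rtol=0, atol=1e-15)
    dual0 = discount_factor(DiscountParams.dual(0.9, 0.95, 0.0), DELAY_GRID)
    np.testing.assert_allclose(dual0, 0.95**DELAY_GRID, rtol=0, atol=1e-15)


def test_zero_bias_matches_plain_hyperbolic_choice_rule():
    rule = ChoiceRule(0.4)
    trial = ChoiceTrial(Prospect(10, 0), Prospect(25, 30))
    p_bias = prob_choose_ll(trial, DiscountParams.ss_bias(0.08, 0.0), rule)
    p_hyp = prob_choose_ll(trial, DiscountParams.hyperbolic(0.08), rule)
    assert p_bias == pytest.approx(p_hyp, abs=1e-15)


@pytest.mark.parametrize(
    "model_id, kappa, bias",
    [("SS_BIAS", 0.08, 14.29), ("IMM_BIAS", 0.08, 14.29)],
)
def test_choice_rule_examples_and_limits(model_id, kappa, bias):
    params = DiscountParams(model_id, kappa=kappa, bias=bias)
    # equal subjective values, theta = 0.1: P(LL) = 1 / (1 + e^(0.1 * bias))
    trial = ChoiceTrial(Prospect(10, 0), Prospect(10 * (1 + kappa * 30), 30))
    p = prob_choose_ll(trial, params, ChoiceRule(0.1))
    assert p == pytest.approx(1.0 / (1.0 + math.exp(0.1 * bias)), abs=1e-9)
    # theta = 0 is random choice regardless of values
    assert prob_choose_ll(trial, params, ChoiceRule(0.0)) == pytest.approx(0.5)


def test_immediacy_bias_gates_on_ss_delay_zero():
    params = DiscountParams.imm_bias(0.08, 14.29)
    assert effective_bias(params, 0.0) == 14.29
    assert effective_bias(params, 2.0) == 0.0
    # SS bias applies regardless of delay
    assert effective_bias(DiscountParams.ss_bias(0.08, 14.29), 2.0) == 14.29
    # valuation-only models carry no bias
    assert effective_bias(DiscountParams.hyperbolic(0.08), 0.0) == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    theta=st.floats(1e-3, 5.0),
    kappa=st.floats(1e-4, 1.0),
    bias=st.floats(-50.0, 50.0),
    ss_amount=st.floats(1.0, 40.0),
    ll_extra=st.floats(0.5, 260.0),
    ss_delay=st.floats(0.0, 15.0),
    ll_gap=st.floats(1.0, 60.0),
)
def test_choice_probabilities_sum_to_one_and_bias_pushes_toward_ss(
    theta, kappa, bias, ss_amount, ll_extra, ss_delay, ll_gap
):
    trial = ChoiceTrial(
        Prospect(ss_amount, ss_delay), Prospect(ss_amount + ll_extra, ss_delay + ll_gap)
    )
    rule = ChoiceRule(theta)
    params = DiscountParams.ss_bias(kappa, bias)
    p_ll = prob_choose_ll(trial, params, rule)
    p_ss = prob_choose_ss(trial, params, rule)
    assert p_ll + p_ss == pytest.approx(1.0, abs=1e-9)
    if bias > 0:
        p_ll_nobias = prob_choose_ll(trial, DiscountParams.ss_bias(kappa, 0.0), rule)
        assert p_ll <= p_ll_nobias
        # strict decrease whenever the shift is representable away from the
        # saturated tails of the logistic
        if bias * theta > 1e-9 and 1e-3 < p_ll_nobias < 1 - 1e-3:
            assert p_ll < p_ll_nobias


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(model_id="HYP", kappa=-0.1),
        dict(model_id="HYP", kappa=0.08, sigma=1.0),  # field not in model
        dict(model_id="HYP2", kappa=0.08, sigma=0.0),
        dict(model_id="DUAL", delta1=0.95, delta2=0.9, omega=0.5),  # ordering
        dict(model_id="DUAL", delta1=0.9, delta2=0.95, omega=1.5),
        dict(model_id="SS_BIAS", kappa=0.08),  # missing bias
        dict(model_id="XXX", kappa=0.08),
    ],
)
def test_invalid_parameters_raise(kwargs):
    with pytest.raises(ValueError):
        DiscountParams(**kwargs)


def test_prospect_and_trial_invariants():
    with pytest.raises(ValueError):
        Prospect(-1.0, 5.0)
    with pytest.raises(ValueError):
        Prospect(10.0, -1.0)
    with pytest.raises(ValueError):
        ChoiceTrial(Prospect(10, 0), Prospect(5, 30))  # amounts out of order
    with pytest.raises(ValueError):
        ChoiceTrial(Prospect(10, 30), Prospect(20, 10))  # delays out of order
    t = ChoiceTrial(Prospect(10, 0), Prospect(20, 30))
    assert t.condition == "NOW"
    t = ChoiceTrial(Prospect(10, 5), Prospect(20, 30))
    assert t.condition == "LATER"
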