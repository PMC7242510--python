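"""Deviance, BIC and cross-validated log loss."""

import math

import numpy as np
import pytest

from delaybias.models import ChoiceRule, DiscountParams, Prospect
from delaybias.trials import ChoiceTrial
from delaybias.fitting import FitConfig, FitResult, GroupFit, fit_group, negloglik
from delaybias.comparison import (
    ComparisonConfig,
    bic,
    compare_models,
    crossvalidate_logloss,
    deviance_g2,
)
from delaybias.staircase import generate_scanner_set, simulate_agent_choice


def _stub_group(logliks):
    fits = {
        f"p{i}": FitResult(
            model_id="HYP",
            params=DiscountParams.hyperbolic(0.08),
            rule=ChoiceRule(0.2),
            loglik=ll,
            n_trials_used=64,
            converged=True,
            n_restarts=1,
            best_start=np.zeros(2),
        )
        for i, ll in enumerate(logliks)
    }
    return GroupFit(model_id="HYP", fits=fits, summary=None, correlations=None)


def test_deviance_closed_forms():
    # one participant, one trial at P = 0.5
    assert deviance_g2(_stub_group([-math.log(2)])) == pytest.approx(
        2 * math.log(2), abs=1e-12
    )
    # noise-only model over 70 participants x 64 trials
    group = _stub_group([-64 * math.log(2)] * 70)
    assert deviance_g2(group) == pytest.approx(2 * 70 * 64 * math.log(2), abs=1e-8)


def test_deviance_matches_brute_force_trial_sum():
    rng = np.random.default_rng(2)
    params = DiscountParams.ss_bias(0.08, 14.29)
    rule = ChoiceRule(0.2)
    design = generate_scanner_set(0.23, seed=3)
    trials_by_p = {
        pid: [t.with_choice(simulate_agent_choice(t, params, rule, rng)) for t in design]
        for pid in ("a", "b", "c")
    }
    group = _stub_group([])
    group.fits = {
        pid: FitResult("SS_BIAS", params, rule, -negloglik(tr, params, rule),
                       64, True, 1, np.zeros(3))
        for pid, tr in trials_by_p.items()
    }
    brute = 2 * sum(
        negloglik(tr, params, rule) for tr in trials_by_p.values()
    )
    assert deviance_g2(group) == pytest.approx(brute, abs=1e-10)


def test_bic_penalty_and_invariances():
    assert bic(123.4, 0, 99) == 123.4
    assert bic(100.0, 3, 72) == pytest.approx(100 + 3 * math.log(72), abs=1e-12)
    assert round(bic(100.0, 3, 72) - 100.0, 2) == 12.83
    # adding a constant to G2 shifts BIC by the same constant
    assert bic(150.0, 3, 72) - bic(100.0, 3, 72) == pytest.approx(50.0)
    # equal parameter counts: BIC differences equal G2 differences exactly
    assert (bic(120.0, 3, 500) - bic(100.0, 3, 500)) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        bic(10.0, 2, 0)


@pytest.fixture(scope="module")
def noisy_cohort():
    """Three participants choosing at random (theta = 0 generating rule)."""
    rng = np.random.default_rng(8)
    design = generate_scanner_set(0.1, seed=9)
    out = {}
    for pid in ("a", "b", "c"):
        out[pid] = [
            t.with_choice("LL" if rng.random() < 0.5 else "SS") for t in design
        ]
    return out


def test_crossvalidation_on_random_choices_near_coin_flip_score(noisy_cohort):
    """Choices carry no structure, so the held-out log-likelihood per
    participant must sit near 64 * ln(1/2)."""
    score = crossvalidate_logloss(
        noisy_cohort, "HYP", k_folds=8, seed=0, fit_config=FitConfig(n_restarts=4)
    )
    assert score <= 0
    assert score == pytest.approx(64 * math.log(0.5), abs=3.0)


def test_crossvalidation_reproducible_and_order_invariant(noisy_cohort):
    cfg = FitConfig(n_restarts=3)
    s1 = crossvalidate_logloss(noisy_cohort, "HYP", k_folds=4, seed=5, fit_config=cfg)
    s2 = crossvalidate_logloss(noisy_cohort, "HYP", k_folds=4, seed=5, fit_config=cfg)
    assert s1 == s2
    reordered = dict(reversed(list(noisy_cohort.items())))
    s3 = crossvalidate_logloss(reordered, "HYP", k_folds=4, seed=5, fit_config=cfg)
    assert s3 == pytest.approx(s1, abs=1e-9)


def test_compare_models_single_model_table(noisy_cohort):
    table = compare_models(
        noisy_cohort,
        ["HYP"],
        ComparisonConfig(include_cv=False, fit=FitConfig(n_restarts=3)),
    )
    assert table.best_model == "HYP"
    assert len(table.table) == 1
    assert bool(table.table["best"].iloc[0])
    assert table.table["rank_by_bic"].iloc[0] == 1


def test_compare_models_bic_conventions(noisy_cohort):
    cfg = ComparisonConfig(
        include_cv=False, fit=FitConfig(n_restarts=3), param_counting="per_model",
        bic_n_obs=72,
    )
    table = compare_models(noisy_cohort, ["HYP", "SS_BIAS"], cfg).table
    t = table.set_index("model_id")
    # printed-style convention: penalty = n_params * ln(72)
    assert t.loc["HYP", "BIC"] - t.loc["HYP", "G2"] == pytest.approx(
        2 * math.log(72), abs=1e-9
    )
    assert t.loc["SS_BIAS", "BIC"] - t.loc["SS_BIAS", "G2"] == pytest.approx(
        3 * math.log(72), abs=1e-9
    )
    # ranks are a permutation and exactly one model is flagged best
    assert sorted(table["rank_by_bic"]) == [1, 2]
    assert table["best"].sum() == 1
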