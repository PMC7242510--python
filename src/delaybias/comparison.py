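"""Group-level model comparison: deviance, BIC and cross-validated log loss.

Models are fit per participant; the group deviance G2 is twice the summed
negative log-likelihood at the per-participant MLEs. BIC adds a
parameter-count penalty scaled by the log of the number of observations.
Because every participant carries their own parameter vector, the default
penalty counts the *total* number of free parameters (participants x
per-model count) against the total number of scorable choices; both the
parameter-counting convention and the observation count can be overridden
(``param_counting="per_model"``, ``bic_n_obs=...``) to emulate reporting
conventions that penalise only the per-model parameter count.

Predictive accuracy is gauged by k-fold cross-validation within participant:
trials are partitioned into folds stratified by the NOW/LATER condition, the
model is refit on k-1 folds, and the held-out log-likelihood is summed. The
reported score is the cohort mean of the per-participant held-out sums -
a log-likelihood, so higher (less negative) is better.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .models import N_PARAMS
from .fitting import FitConfig, fit_group, fit_participant, negloglik
from .trials import ChoiceTrial

__all__ = [
    "ComparisonConfig",
    "ComparisonTable",
    "deviance_g2",
    "bic",
    "crossvalidate_logloss",
    "compare_models",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonConfig:
    k_folds: int = 8
    include_cv: bool = True
    bic_n_obs: Optional[int] = None
    param_counting: str = "per_participant"  # or "per_model"
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class ComparisonTable:
    """Tidy comparison across models; ``best_model`` has the lowest BIC."""

    table: pd.DataFrame
    best_model: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def deviance_g2(group_fit) -> float:
    """G2 = 2 * sum over participants of the negative log-likelihood at the
    MLE."""
    if not group_fit.fits:
        raise ValueError("no fits in group")
    return 2.0 * sum(-f.loglik for f in group_fit.fits.values())


def bic(g2: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion on the deviance scale:
    ``G2 + n_params * ln(n_obs)``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return g2 + n_params * math.log(n_obs)


def _stratified_folds(
    trials: Sequence[ChoiceTrial], k: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Seeded k-fold partition of trial indices, stratified by condition."""
    idx = np.arange(len(trials))
    folds: List[list] = [[] for _ in range(k)]
    for cond in ("NOW", "LATER"):
        members = idx[[t.condition == cond for t in trials]]
        members = rng.permutation(members)
        for j, i in enumerate(members):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f)]


def crossvalidate_logloss(
    trials_by_participant: Dict[str, Sequence[ChoiceTrial]],
    model_id: str,
    k_folds: int = 8,
    seed: int = 0,
    fit_config: Optional[FitConfig] = None,
) -> float:
    """Mean per-participant held-out log-likelihood under k-fold CV.

    Folds whose training set contains a single choice class cannot support a
    refit; such a fold is merged into the next one and the merge is logged.
    """
    cfg = fit_config or FitConfig()
    scores = []
    for pid, trials in trials_by_participant.items():
        scored = [t for t in trials if t.chosen in ("SS", "LL")]
        if len(scored) < k_folds:
            raise ValueError(
                f"participant {pid}: {len(scored)} scorable trials < k_folds={k_folds}"
            )
        # per-participant stream keyed by id: invariant to cohort ordering
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, zlib.crc32(str(pid).encode())))
        )
        folds = _stratified_folds(scored, k_folds, rng)
        held_out = 0.0
        pending: List[int] = []
        for fold in folds:
            test_idx = set(pending) | set(fold.tolist())
            train = [t for i, t in enumerate(scored) if i not in test_idx]
            classes = {t.chosen for t in train}
            if len(classes) < 2:
                log.warning(
                    "participant %s: single-class training fold; merging fold forward",
                    pid,
                )
                pending = sorted(test_idx)
                continue
            fit = fit_participant(
                train, model_id, replace(cfg, min_trials=2, seed=cfg.seed)
            )
            test = [scored[i] for i in sorted(test_idx)]
            held_out += -negloglik(test, fit.params, fit.rule)
            pending = []
        if pending:
            # trailing un-scorable folds: score them under a fit to all
            # other trials
            train = [t for i, t in enumerate(scored) if i not in set(pending)]
            fit = fit_participant(
                train, model_id, replace(cfg, min_trials=2, seed=cfg.seed)
            )
            held_out += -negloglik(
                [scored[i] for i in pending], fit.params, fit.rule
            )
        scores.append(held_out)
    return float(np.mean(scores))


def compare_models(
    trials_by_participant: Dict[str, Sequence[ChoiceTrial]],
    model_ids: Sequence[str],
    config: Optional[ComparisonConfig] = None,
) -> ComparisonTable:
    """Fit every model to every participant and tabulate G2, BIC and
    (optionally) cross-validated log loss. The best model minimises BIC;
    ties break toward fewer parameters."""
    if len(model_ids) < 1:
        raise ValueError("at least one model required")
    cfg = config or ComparisonConfig()
    n_participants = len(trials_by_participant)
    n_choices = sum(
        sum(t.chosen in ("SS", "LL") for t in trials)
        for trials in trials_by_participant.values()
    )
    n_obs = cfg.bic_n_obs if cfg.bic_n_obs is not None else n_choices
    rows = []
    for model_id in model_ids:
        gf = fit_group(trials_by_participant, model_id, cfg.fit)
        g2 = deviance_g2(gf)
        p = N_PARAMS[model_id]
        total_params = p * len(gf.fits) if cfg.param_counting == "per_participant" else p
        row = {
            "model_id": model_id,
            "n_params": p,
            "G2": g2,
            "BIC": bic(g2, total_params, n_obs),
        }
        if cfg.include_cv:
            row["cv_logloss"] = crossvalidate_logloss(
                trials_by_participant,
                model_id,
                k_folds=cfg.k_folds,
                seed=cfg.seed,
                fit_config=cfg.fit,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table.sort_values(["BIC", "n_params"], kind="mergesort")
    ranks = {mid: r for mid, r in zip(order["model_id"], range(1, len(order) + 1))}
    table["rank_by_bic"] = table["model_id"].map(ranks)
    table["best"] = table["rank_by_bic"] == 1
    best_model = order.iloc[0]["model_id"]
    log.info(
        "model comparison over %d participants, %d choices: best=%s",
        n_participants,
        n_choices,
        best_model,
    )
    return ComparisonTable(table=table, best_model=best_model)
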