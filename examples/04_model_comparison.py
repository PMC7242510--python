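"""Compare the five choice models on a small synthetic cohort.

Choices are generated from the SS-bias process, so that model should win
the BIC comparison; the cross-validated log loss (held-out log-likelihood,
higher is better) gives a complementary predictive view.
"""

from delaybias import (
    CohortConfig,
    ComparisonConfig,
    FitConfig,
    MODEL_IDS,
    compare_models,
    simulate_cohort,
)

cohort = simulate_cohort(CohortConfig(n_participants=8, seed=3, fit=FitConfig(n_restarts=6)))
print(f"simulated {len(cohort.participants)} participants x 64 tailored trials\n")

table = compare_models(
    cohort.trials_by_participant,
    MODEL_IDS,
    ComparisonConfig(k_folds=4, seed=0, fit=FitConfig(n_restarts=6)),
)
cols = ["model_id", "n_params", "G2", "BIC", "cv_logloss", "rank_by_bic", "best"]
print(table.table[cols].round(2).to_string(index=False))
print(
    f"\nbest model by BIC: {table.best_model} "
    "(lower G2/BIC = better fit; cv_logloss closer to 0 = better prediction)"
)
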