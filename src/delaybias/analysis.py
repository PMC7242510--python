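"""Behavioral statistics linking fitted choice parameters to covariates.

Standardization, Pearson/Spearman correlations with Fisher-z confidence
intervals, multiple regression of a fitted parameter on log-testosterone
controlling for age (standardized OLS with variance inflation factors),
Tukey interquartile-range outlier removal, and the middle-age-quartile
subsampling used to reduce age-testosterone collinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "PredictorStats",
    "RegressionResult",
    "OutlierResult",
    "standardize",
    "correlate",
    "regress_param_on_covariates",
    "iqr_outlier_filter",
    "quartile_subsample",
]


def standardize(values) -> np.ndarray:
    """z-scores: (x - mean) / SD (population SD). Errors on constant input."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize: zero or non-finite variance")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation with a Fisher-transformation 95% CI.

    The Fisher interval is atanh(r) +/- 1.96 / sqrt(n - 3), back-transformed;
    for Spearman it is applied to the rank correlation as an approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    r = float(r)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p=float(p), n=n, method=method)


@dataclass(frozen=True)
class PredictorStats:
    name: str
    b: float
    ci_low: float
    ci_high: float
    p: float
    vif: float


@dataclass
class RegressionResult:
    outcome: str
    n: int
    predictors: list
    r_squared: float
    subsample_flag: bool = False

    def predictor(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "predictor": p.name,
                    "b": p.b,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "p": p.p,
                    "vif": p.vif,
                    "n": self.n,
                    "subsample_flag": self.subsample_flag,
                }
                for p in self.predictors
            ]
        )


def regress_param_on_covariates(
    values,
    log_testosterone,
    age,
    subset_mask=None,
    outcome: str = "param",
) -> RegressionResult:
    """Standardized OLS of a fitted parameter on log-testosterone and age.

    All three variables are standardized within the analysed subset, so the
    coefficients are standardized betas with normal-theory 95% CIs and
    two-sided p-values. Each predictor's variance inflation factor is
    1 / (1 - R2_j) from the auxiliary regression of that predictor on the
    other.
    """
    y = np.asarray(values, dtype=float)
    x1 = np.asarray(log_testosterone, dtype=float)
    x2 = np.asarray(age, dtype=float)
    mask = (
        np.ones(len(y), dtype=bool)
        if subset_mask is None
        else np.asarray(subset_mask, dtype=bool)
    )
    y, x1, x2 = y[mask], x1[mask], x2[mask]
    n = len(y)
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    zy, z1, z2 = standardize(y), standardize(x1), standardize(x2)
    r12 = float(np.corrcoef(z1, z2)[0, 1])
    r2_aux = r12**2
    if r2_aux > 0.999:
        raise ValueError(
            "predictors log_testosterone and age are collinear "
            f"(auxiliary R^2 = {r2_aux:.4f})"
        )
    vif = 1.0 / (1.0 - r2_aux)
    X = sm.add_constant(np.column_stack([z1, z2]))
    model = sm.OLS(zy, X).fit()
    ci = model.conf_int(alpha=0.05)
    preds = [
        PredictorStats(
            name=name,
            b=float(model.params[j]),
            ci_low=float(ci[j][0]),
            ci_high=float(ci[j][1]),
            p=float(model.pvalues[j]),
            vif=vif,
        )
        for j, name in ((1, "log_testosterone"), (2, "age"))
    ]
    return RegressionResult(
        outcome=outcome,
        n=n,
        predictors=preds,
        r_squared=float(model.rsquared),
        subsample_flag=subset_mask is not None,
    )


@dataclass
class OutlierResult:
    keep_mask: np.ndarray
    removed: np.ndarray
    lower_fence: float
    upper_fence: float
    retained_min: float
    retained_max: float


def iqr_outlier_filter(values, multiplier: float = 1.5) -> OutlierResult:
    """Tukey fences: drop values outside [Q1 - m*IQR, Q3 + m*IQR].

    Returns an OutlierResult with the keep mask, removed values, fences and
    the min/max of the retained values. With zero IQR (all values equal up
    to the quartiles) nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (x >= lo) & (x <= hi)
    kept = x[keep]
    return OutlierResult(
        keep_mask=keep,
        removed=x[~keep],
        lower_fence=float(lo),
        upper_fence=float(hi),
        retained_min=float(kept.min()) if len(kept) else math.nan,
        retained_max=float(kept.max()) if len(kept) else math.nan,
    )


def quartile_subsample(ages) -> np.ndarray:
    """Mask keeping participants in the middle two age quartiles [Q1, Q3].

    Quartiles use linear-interpolation quantiles; boundary ties are kept
    (inclusive on both ends).
    """
    x = np.asarray(ages, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    q1, q3 = np.percentile(x, [25, 75])
    return (x >= q1) & (x <= q3)
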