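"""Two-step hierarchical log-linear regression of excess length-of-stay cost.

The outcome is the natural log of each above-average episode's extra cost.
Demographics (age in years, male indicator) enter in step one; surgery,
dementia, admission severity (DRG cost weight), the modified Charlson index
and the number of hospital-acquired complications enter in step two.  Both
blocks are pre-specified: this is fixed-order block entry, not data-driven
variable selection.

Because standard errors do not survive the reverse log transformation,
relative importance is reported through standardised betas, and dollar
effects are obtained by evaluating the multiplicative effect of each
predictor at the sample mean extra cost:

    b_dollars = (exp(b_log) - 1) * mean(extra_cost)

with the per-unit effect also expressed as an integer percentage of the
mean extra cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

BACK_TRANSFORM_METHODS = ("mean", "median", "predicted_at_means")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered predictor blocks for the hierarchical fit.

    Names refer to columns of the analysis table; ``sex`` is pre-coded as a
    ``male`` indicator (male=1, female=0).  ``complication_coding`` selects
    whether complications enter as the 0-4 count or as an any-complication
    indicator.
    """

    step1_predictors: tuple[str, ...] = ("age", "male")
    step2_predictors: tuple[str, ...] = (
        "surgical",
        "dementia",
        "cost_weight",
        "charlson",
        "n_complications",
    )
    outcome: str = "extra_cost"
    complication_coding: str = "count"
    back_transform_method: str = "mean"

    def __post_init__(self):
        if self.complication_coding not in ("count", "any"):
            raise ValueError(f"unknown complication_coding {self.complication_coding!r}")
        if self.back_transform_method not in BACK_TRANSFORM_METHODS:
            raise ValueError(f"unknown back_transform_method {self.back_transform_method!r}")

    @property
    def all_predictors(self) -> tuple[str, ...]:
        return self.step1_predictors + self.step2_predictors


@dataclass
class RegressionResult:
    """Fit summary: per-predictor effects and per-step goodness of fit.

    ``coefficients`` is indexed by predictor with columns ``b_log``, ``se``,
    ``ci_low``, ``ci_high``, ``beta_std``, ``b_dollars``, ``pct_of_mean``.
    """

    coefficients: pd.DataFrame
    intercept: float
    r2_step1: float
    r2_step2: float
    adj_r2: float
    f_value: float
    n: int
    n_dropped_missing: int
    mean_extra_cost: float
    back_transform_method: str

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                p: {k: (int(v) if k == "pct_of_mean" else float(v)) for k, v in row.items()}
                for p, row in self.coefficients.to_dict(orient="index").items()
            },
            "intercept": float(self.intercept),
            "r2_step1": float(self.r2_step1),
            "r2_step2": float(self.r2_step2),
            "adj_r2": float(self.adj_r2),
            "f_value": float(self.f_value),
            "n": int(self.n),
            "n_dropped_missing": int(self.n_dropped_missing),
            "mean_extra_cost": float(self.mean_extra_cost),
            "back_transform_method": self.back_transform_method,
        }


class SingularModelError(ValueError):
    """The design matrix is rank deficient."""


def standardize(b_log: float, predictor_sd: float, outcome_sd: float) -> float:
    """Standardised beta: ``b_log * sd(x) / sd(ln y)``."""
    if predictor_sd <= 0:
        raise ValueError("zero-variance predictor cannot be standardised")
    if outcome_sd <= 0:
        raise ValueError("outcome standard deviation must be positive")
    return b_log * predictor_sd / outcome_sd


def back_transform(b_log: float, scale: float) -> float:
    """Dollar effect per unit of a predictor, evaluated at ``scale`` dollars.

    ``(exp(b_log) - 1) * scale``: the multiplicative per-unit effect of a
    log-scale coefficient applied to a reference cost (by default the sample
    mean extra cost).
    """
    if scale <= 0:
        raise ValueError("reference cost scale must be positive")
    return (math.exp(b_log) - 1.0) * scale


def percentage_of_mean(b_dollars: float, mean_extra_cost: float) -> int:
    """Integer percentage of the mean extra cost, rounded half away from zero."""
    if mean_extra_cost <= 0:
        raise ValueError("mean extra cost must be positive")
    x = 100.0 * b_dollars / mean_extra_cost
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # Identify predictors whose removal restores full rank.
        offenders = []
        for col in X.columns:
            sub = np.column_stack(
                [np.ones(len(X)), X.drop(columns=[col]).to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                offenders.append(col)
        raise SingularModelError(
            f"design matrix is rank deficient; collinear predictors involve: "
            f"{offenders or list(X.columns)}"
        )


def _design(data: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    X = data.loc[:, list(predictors)].astype(float)
    return X


def fit_hierarchical(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    robust: bool = False,
) -> RegressionResult:
    """Fit the two-step model on ln(extra_cost) and assemble the result table.

    ``data`` holds one row per above-average episode with all predictor
    columns and a positive ``extra_cost``.  Rows with missing model fields
    are dropped listwise (count reported).  Plain OLS standard errors by
    default; ``robust=True`` switches to HC1 heteroscedasticity-consistent
    errors.
    """
    if spec is None:
        spec = ModelSpec()
    work = data.copy()
    if spec.complication_coding == "any" and "n_complications" in spec.all_predictors:
        work["n_complications"] = (work["n_complications"] > 0).astype(int)

    model_cols = list(spec.all_predictors) + [spec.outcome]
    n_input = len(work)
    work = work.dropna(subset=model_cols)
    n_dropped = n_input - len(work)
    if (work[spec.outcome] <= 0).any():
        raise ValueError("extra_cost must be strictly positive (log outcome)")
    n = len(work)
    if n <= len(spec.all_predictors) + 1:
        raise ValueError(
            f"n={n} too small for {len(spec.all_predictors)} predictors"
        )

    y = np.log(work[spec.outcome].to_numpy(dtype=float))
    X_full = _design(work, spec.all_predictors)
    _check_rank(X_full)
    X1 = sm.add_constant(_design(work, spec.step1_predictors))
    X2 = sm.add_constant(X_full)

    fit1 = sm.OLS(y, X1).fit()
    fit2 = sm.OLS(y, X2).fit(cov_type="HC1" if robust else "nonrobust")

    mean_cost = float(work[spec.outcome].mean())
    if spec.back_transform_method == "mean":
        scale = mean_cost
    elif spec.back_transform_method == "median":
        scale = float(work[spec.outcome].median())
    else:  # predicted_at_means: fitted cost at the covariate means
        xbar = np.concatenate([[1.0], X_full.mean().to_numpy()])
        scale = float(np.exp(xbar @ fit2.params.to_numpy()))

    sd_y = float(np.std(y, ddof=1))
    ci = fit2.conf_int(alpha=0.05)
    rows = {}
    for p in spec.all_predictors:
        b = float(fit2.params[p])
        sd_x = float(X_full[p].std(ddof=1))
        dollars = back_transform(b, scale)
        rows[p] = {
            "b_log": b,
            "se": float(fit2.bse[p]),
            "ci_low": float(ci.loc[p, 0]),
            "ci_high": float(ci.loc[p, 1]),
            "beta_std": standardize(b, sd_x, sd_y),
            "b_dollars": dollars,
            "pct_of_mean": percentage_of_mean(dollars, mean_cost),
        }
    coef = pd.DataFrame.from_dict(rows, orient="index").loc[list(spec.all_predictors)]

    return RegressionResult(
        coefficients=coef,
        intercept=float(fit2.params["const"]),
        r2_step1=float(fit1.rsquared),
        r2_step2=float(fit2.rsquared),
        adj_r2=float(fit2.rsquared_adj),
        f_value=float(fit2.fvalue),
        n=n,
        n_dropped_missing=n_dropped,
        mean_extra_cost=mean_cost,
        back_transform_method=spec.back_transform_method,
    )
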