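"""Daily pant-hoot and aggression rate models with log-exposure offsets.

Both models are negative-binomial GLMMs with a log link on per-focal-day
counts, with ``ln(hours observed)`` as an offset so coefficients read as
log rate ratios per observation hour.  The pant-hoot model tests period,
standardized rank and whether the focal male leaf clipped that day; the
aggression model tests period and leaf clipping while keeping rank as a
control (higher-ranking males are expected to be involved in more
aggression, so rank stays in the null model).  Random structure mirrors the
acoustic models: focal-male intercept plus independent centered slopes of
all fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import (
    MixedModelFit,
    TestResult,
    build_random_design,
    fit_count_glmm,
    likelihood_ratio_test,
)

__all__ = [
    "RateModelSpec",
    "rate_registry",
    "fit_rate_model",
    "rate_full_null_test",
    "rate_drop1",
]

_RATE_PREDICTOR_COLUMNS = {
    "period": ("period_during", "period_after"),
    "rank_std": ("rank_std",),
    "leaf_clip_day": ("leaf_clip_day",),
}


@dataclass(frozen=True)
class RateModelSpec:
    """Specification of one daily-rate model."""

    response: str  # "n_pant_hoots" or "n_aggression"
    test_predictors: tuple
    control_predictors: tuple = ()
    family: str = "negative_binomial"

    @property
    def test_df(self) -> int:
        return sum(len(_RATE_PREDICTOR_COLUMNS[p]) for p in self.test_predictors)


def rate_registry() -> list:
    """The two daily-rate model specifications."""
    return [
        RateModelSpec(
            response="n_pant_hoots",
            test_predictors=("period", "rank_std", "leaf_clip_day"),
        ),
        RateModelSpec(
            response="n_aggression",
            test_predictors=("period", "leaf_clip_day"),
            control_predictors=("rank_std",),
        ),
    ]


def _design(spec: RateModelSpec, days: pd.DataFrame, predictors: list):
    hours = days["hours_observed"].to_numpy(float)
    if np.any(hours <= 0):
        raise ValueError("hours_observed must be strictly positive")
    values = {
        "period_during": (days["period"] == "during").to_numpy(float),
        "period_after": (days["period"] == "after").to_numpy(float),
        "rank_std": days["rank_std"].to_numpy(float),
        "leaf_clip_day": days["leaf_clip_day"].to_numpy(float),
    }
    cols, names = [np.ones(len(days))], ["(Intercept)"]
    for pred in predictors:
        for c in _RATE_PREDICTOR_COLUMNS[pred]:
            cols.append(values[c])
            names.append(c)
    X = np.column_stack(cols)
    codes, _ = pd.factorize(days["focal_id"], sort=True)
    slopes = {
        c: values[c]
        for cols_ in _RATE_PREDICTOR_COLUMNS.values()
        for c in cols_
    }
    Z, term_of_col, re_names = build_random_design(codes, slopes)
    return X, names, Z, term_of_col, re_names, np.log(hours)


def fit_rate_model(
    spec: RateModelSpec,
    days: pd.DataFrame,
    include_test_predictors: bool = True,
    drop: str | None = None,
) -> MixedModelFit:
    """ML fit of a daily-rate GLMM with a log-hours offset.

    The null model (``include_test_predictors=False``) keeps the offset,
    any control predictors and the full random structure.
    """
    if drop is not None and drop not in spec.test_predictors:
        raise ValueError(f"{drop!r} is not a test predictor of this model")
    days = days.reset_index(drop=True)
    if days["focal_id"].nunique() < 2:
        raise ValueError("need at least two focal individuals")
    preds = [
        p for p in spec.test_predictors if include_test_predictors and p != drop
    ]
    preds += [p for p in spec.control_predictors if p not in preds]
    X, names, Z, term_of_col, re_names, offset = _design(spec, days, preds)
    y = days[spec.response].to_numpy(float)
    return fit_count_glmm(
        y, X, Z, term_of_col, names, re_names, family=spec.family, offset=offset
    )


def rate_full_null_test(spec: RateModelSpec, days: pd.DataFrame) -> TestResult:
    """Full-vs-null likelihood-ratio test (df 4 for pant hoots, 3 for
    aggression, whose null keeps rank as a control)."""
    full = fit_rate_model(spec, days, include_test_predictors=True)
    null = fit_rate_model(spec, days, include_test_predictors=False)
    return likelihood_ratio_test(full, null, df=spec.test_df)


def rate_drop1(
    spec: RateModelSpec, days: pd.DataFrame, full: MixedModelFit | None = None
) -> dict:
    """Per-predictor likelihood-ratio tests against the full rate model."""
    if full is None:
        full = fit_rate_model(spec, days, include_test_predictors=True)
    out = {}
    for pred in spec.test_predictors:
        reduced = fit_rate_model(spec, days, drop=pred)
        df = len(_RATE_PREDICTOR_COLUMNS[pred])
        out[pred] = likelihood_ratio_test(full, reduced, df=df)
    return out
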