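"""The registry of 18 acoustic mixed models and their test machinery.

Each acoustic response is modelled separately.  The fixed effects are always
the three **test predictors** — instability period (before / during / after,
"before" as reference), standardized rank, and whether a leaf clip directly
preceded the call — plus one **control predictor**, whether the recording
captured the complete pant hoot.  Every model carries a random intercept for
the caller and independent random slopes of all fixed effects within
caller, with factor predictors entered into the slope design as
mean-centered dummies.

Inference is by likelihood-ratio tests: the full model against a null model
lacking the three test predictors but otherwise identical (same control,
same random structure), and per-predictor tests dropping one test predictor
at a time from the full model.  Diagnostics cover overdispersion of the
count models, generalized variance-inflation factors on a fixed-effects-only
linear model, and leave-one-caller-out stability of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import apply_transform
from .mixed import (
    MixedModelFit,
    TestResult,
    build_random_design,
    fit_count_glmm,
    fit_gaussian_lmm,
    likelihood_ratio_test,
)

__all__ = [
    "ModelSpec",
    "TEST_PREDICTORS",
    "model_registry",
    "fit_model",
    "full_null_fits",
    "full_null_test",
    "drop1_tests",
    "dispersion_parameter",
    "vif_check",
    "stability_check",
    "model_table",
    "sign_table",
]

#: Test predictors with the degrees of freedom their removal frees.
TEST_PREDICTORS = {"period": 2, "rank_std": 1, "leaf_clip": 1}

_PREDICTOR_COLUMNS = {
    "period": ("period_during", "period_after"),
    "rank_std": ("rank_std",),
    "leaf_clip": ("leaf_clip",),
    "complete_recording": ("complete_recording",),
}


@dataclass(frozen=True)
class ModelSpec:
    """One row of the acoustic-model registry."""

    response: str
    label: str
    transform: str
    family: str
    expected_n: int

    @property
    def link(self) -> str:
        return "identity" if self.family == "gaussian" else "log"


_REGISTRY_ROWS = [
    # response column, display label, transform, family, expected n
    ("total_duration_s", "Total duration (s)", "sqrt", "gaussian", 212),
    ("n_intro_calls", "# calls in the introduction", "none", "poisson", 173),
    ("intro_duration_s", "Introduction duration (s)", "sqrt", "gaussian", 173),
    ("intro_last_call_f0_hz", "F0 of last call of the introduction (Hz)", "sqrt", "gaussian", 173),
    ("intro_last_call_duration_s", "Duration of the last call of the introduction (s)", "none", "gaussian", 173),
    ("intro_last_call_pf_hz", "pF of the last call of the introduction (Hz)", "log", "gaussian", 173),
    ("n_buildup_calls", "# of voiced calls in the build-up", "none", "negative_binomial", 189),
    ("buildup_duration_s", "Duration of the build-up (s)", "sqrt", "gaussian", 189),
    ("buildup_mid_call_f0_hz", "F0 of the middle call of the build-up (Hz)", "sqrt", "gaussian", 189),
    ("buildup_mid_call_duration_s", "Duration of the middle call of the build-up", "log_x1000", "gaussian", 189),
    ("buildup_mid_call_pf_hz", "pF of the middle call of the build-up (Hz)", "log", "gaussian", 189),
    ("n_climax_elements", "# of elements in the climax", "none", "negative_binomial", 189),
    ("climax_duration_s", "Duration of the climax (s)", "sqrt", "gaussian", 189),
    ("climax_f0_hz", "F0 of the highest call of the climax (Hz)", "none", "gaussian", 127),
    ("climax_call_duration_s", "Duration of the highest call of the climax (s)", "none", "gaussian", 127),
    ("climax_pf_hz", "pF of the highest call of the climax (Hz)", "log", "gaussian", 127),
    ("drumming_duration_s", "Duration of drumming (s)", "sqrt", "gaussian", 210),
    ("n_drum_beats", "# of drum beats", "none", "negative_binomial", 210),
]


def model_registry() -> list:
    """The 18 acoustic model specifications, in pant-hoot phase order."""
    return [ModelSpec(*row) for row in _REGISTRY_ROWS]


def registry_by_response() -> dict:
    return {s.response: s for s in model_registry()}


# ---------------------------------------------------------------------------
# Design construction


def _model_rows(spec: ModelSpec, calls: pd.DataFrame) -> pd.DataFrame:
    resp = calls[spec.response]
    sub = calls.loc[resp.notna()].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"response {spec.response!r} is missing in every row")
    return sub


def _fixed_design(sub: pd.DataFrame, predictors: list) -> tuple:
    cols, names = [np.ones(len(sub))], ["(Intercept)"]
    values = {
        "period_during": (sub["period"] == "during").to_numpy(float),
        "period_after": (sub["period"] == "after").to_numpy(float),
        "rank_std": sub["rank_std"].to_numpy(float),
        "leaf_clip": sub["leaf_clip"].to_numpy(float),
        "complete_recording": sub["complete_recording"].to_numpy(float),
    }
    for pred in predictors:
        for c in _PREDICTOR_COLUMNS[pred]:
            cols.append(values[c])
            names.append(c)
    return np.column_stack(cols), names, values


def _random_design(sub: pd.DataFrame, values: dict) -> tuple:
    codes, _ = pd.factorize(sub["caller_id"], sort=True)
    slopes = {c: values[c] for cols in _PREDICTOR_COLUMNS.values() for c in cols}
    return build_random_design(codes, slopes)


def fit_model(
    spec: ModelSpec,
    calls: pd.DataFrame,
    include_test_predictors: bool = True,
    drop: str | None = None,
    start: np.ndarray | None = None,
) -> MixedModelFit:
    """Fit one registry model by maximum likelihood (never REML).

    Rows with a missing response are dropped first, so nested fits on the
    same spec share an identical row set and their likelihoods are
    comparable.  The random structure (caller intercept + centered-dummy
    slopes of *all* fixed effects) is identical in full, null and reduced
    fits.

    Parameters
    ----------
    include_test_predictors : bool
        False fits the null model (control predictor only).
    drop : str, optional
        Name of one test predictor to omit from the full model (for the
        per-predictor likelihood-ratio tests).
    start : array, optional
        Optimizer start (``opt_x`` of a fit of the same model on similar
        data); used to warm-start refits inside the permutation loop.
    """
    if drop is not None and drop not in TEST_PREDICTORS:
        raise ValueError(f"unknown test predictor {drop!r}")
    sub = _model_rows(spec, calls)
    preds = [p for p in TEST_PREDICTORS if include_test_predictors and p != drop]
    preds.append("complete_recording")
    X, names, values = _fixed_design(sub, preds)
    Z, term_of_col, re_names = _random_design(sub, values)
    if spec.family == "gaussian":
        y = apply_transform(sub[spec.response].to_numpy(float), spec.transform)
        return fit_gaussian_lmm(y, X, Z, term_of_col, names, re_names, start=start)
    y = sub[spec.response].to_numpy(float)
    return fit_count_glmm(
        y, X, Z, term_of_col, names, re_names, family=spec.family, start=start
    )


def full_null_fits(
    spec: ModelSpec, calls: pd.DataFrame, starts: tuple | None = None
) -> tuple:
    """Fit the full and null models on the identical row subset."""
    s_full, s_null = starts if starts is not None else (None, None)
    full = fit_model(spec, calls, include_test_predictors=True, start=s_full)
    null = fit_model(spec, calls, include_test_predictors=False, start=s_null)
    return full, null


def full_null_test(
    spec: ModelSpec, calls: pd.DataFrame, starts: tuple | None = None
) -> TestResult:
    """Likelihood-ratio test of the full model against the test-predictor-free
    null on the identical row subset (df = 4: period 2, rank 1, leaf clip 1)."""
    full, null = full_null_fits(spec, calls, starts=starts)
    return likelihood_ratio_test(full, null, df=sum(TEST_PREDICTORS.values()))


def drop1_tests(
    spec: ModelSpec, calls: pd.DataFrame, full: MixedModelFit | None = None
) -> dict:
    """One likelihood-ratio test per test predictor against the full model."""
    if full is None:
        full = fit_model(spec, calls, include_test_predictors=True)
    out = {}
    for pred, df in TEST_PREDICTORS.items():
        reduced = fit_model(spec, calls, drop=pred)
        out[pred] = likelihood_ratio_test(full, reduced, df=df)
    return out


# ---------------------------------------------------------------------------
# Diagnostics


def dispersion_parameter(fit: MixedModelFit, y: np.ndarray) -> float:
    """Overdispersion of a count fit: sum of squared Pearson residuals over
    residual degrees of freedom (n minus the number of fixed effects).

    Values near 1 indicate a well-specified count model.
    """
    if fit.family == "gaussian":
        raise ValueError("dispersion parameter applies to count models only")
    y = np.asarray(y, float)
    mu = fit.mu_hat
    var = mu if fit.family == "poisson" else mu + mu**2 / fit.nb_theta
    pearson2 = (y - mu) ** 2 / np.clip(var, 1e-12, None)
    return float(pearson2.sum() / (fit.n_obs - fit.n_fixef))


def vif_check(calls: pd.DataFrame) -> dict:
    """Generalized variance-inflation factors of the predictors.

    Computed car-style on a fixed-effects-only linear model: the GVIF of a
    predictor group is a determinant ratio of the predictor correlation
    matrix; the returned value is ``GVIF ** (1/df)``, which reduces to the
    ordinary VIF for single-column predictors and is the df-adjusted analog
    for the three-level period factor.  Perfectly collinear predictors are
    reported as ``inf``.
    """
    _, names, values = _fixed_design(
        calls, list(TEST_PREDICTORS) + ["complete_recording"]
    )
    cols = names[1:]  # drop intercept
    M = np.column_stack([values[c] for c in cols])
    sd = M.std(axis=0)
    if np.any(sd == 0):
        zero = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"predictors without variation: {zero}")
    R = np.corrcoef(M, rowvar=False)
    detR = np.linalg.det(R)
    out = {}
    for pred in list(TEST_PREDICTORS) + ["complete_recording"]:
        idx = [cols.index(c) for c in _PREDICTOR_COLUMNS[pred]]
        rest = [i for i in range(len(cols)) if i not in idx]
        if detR <= 1e-12:
            out[pred] = float("inf")
            continue
        g = (
            np.linalg.det(R[np.ix_(idx, idx)])
            * np.linalg.det(R[np.ix_(rest, rest)])
            / detR
        )
        out[pred] = float(g ** (1.0 / len(idx)))
    return out


def stability_check(
    spec: ModelSpec, calls: pd.DataFrame, full: MixedModelFit | None = None
) -> dict:
    """Leave-one-caller-out stability of the test-predictor estimates.

    Refits the full model with each caller excluded and reports the largest
    absolute change across all test-predictor coefficients; ``nan`` marks a
    refit that did not converge.
    """
    callers = sorted(calls["caller_id"].unique())
    if len(callers) < 3:
        raise ValueError("stability check needs at least 3 callers")
    if full is None:
        full = fit_model(spec, calls, include_test_predictors=True)
    test_cols = [c for p in TEST_PREDICTORS for c in _PREDICTOR_COLUMNS[p]]
    ref = {c: full.coefficients[c][0] for c in test_cols if c in full.coefficients}
    sub_all = _model_rows(spec, calls)
    out = {}
    for caller in callers:
        if not (sub_all["caller_id"] == caller).any():
            out[caller] = 0.0  # caller contributes no usable rows
            continue
        reduced_data = calls.loc[calls["caller_id"] != caller]
        try:
            refit = fit_model(spec, reduced_data, include_test_predictors=True)
        except Exception:
            out[caller] = float("nan")
            continue
        if not refit.converged:
            out[caller] = float("nan")
            continue
        deltas = [
            abs(refit.coefficients[c][0] - ref[c])
            for c in ref
            if c in refit.coefficients
        ]
        out[caller] = float(max(deltas)) if deltas else 0.0
    return out


# ---------------------------------------------------------------------------
# Report tables


def _fmt_p(p: float) -> str:
    return f"{p:.2g}"


def model_table(results: list) -> pd.DataFrame:
    """Registry-style summary: one row per model with its full-vs-null test.

    ``results`` holds ``(spec, n_obs, TestResult)`` triples.
    """
    rows = []
    for spec, n, test in results:
        rows.append(
            {
                "response": spec.label,
                "transform": spec.transform,
                "family": spec.family,
                "link": spec.link,
                "n": n,
                "chisq": round(test.statistic, 2),
                "df": test.df,
                "p": test.p_value,
                "p_formatted": _fmt_p(test.p_value),
            }
        )
    return pd.DataFrame(rows)


def sign_table(per_model: list) -> pd.DataFrame:
    """Direction-of-effect summary across models.

    ``per_model`` holds ``(spec, fit, drop1 dict)`` triples.  For each test
    predictor the entry is ``up``/``down`` when its likelihood-ratio test
    has p < 0.05, ``up?``/``down?`` for 0.05 <= p < 0.1 (a tendency), and
    empty otherwise.  For the two-column period predictor the direction is
    taken from the larger-magnitude period coefficient.
    """
    rows = []
    for spec, fit, tests in per_model:
        row = {"response": spec.label}
        for pred in TEST_PREDICTORS:
            test = tests[pred]
            cols = [c for c in _PREDICTOR_COLUMNS[pred] if c in fit.coefficients]
            ests = [fit.coefficients[c][0] for c in cols]
            direction = "up" if ests[int(np.argmax(np.abs(ests)))] > 0 else "down"
            if test.p_value < 0.05:
                row[pred] = direction
            elif test.p_value < 0.1:
                row[pred] = direction + "?"
            else:
                row[pred] = ""
        rows.append(row)
    return pd.DataFrame(rows)
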