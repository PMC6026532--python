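"""The mixed-model engine: oracles, likelihood properties, design checks."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import statsmodels.api as sm

from panthoot.data import apply_transform
from panthoot.mixed import TestResult as LikelihoodRatioResult
from panthoot.mixed import build_random_design
from panthoot.models import (
    drop1_tests,
    fit_model,
    full_null_test,
    model_registry,
    registry_by_response,
)
from panthoot.simulate import default_config, simulate_call_table

SLOPE_COLS = ["during", "after", "rank_std", "lc", "comp"]


def _export_model_frame(calls, response):
    """The model frame fit_model sees: response subset, centered slopes."""
    sub = calls[calls[response].notna()].copy()
    sub["y"] = sub[response]
    sub["during"] = (sub.period == "during").astype(float)
    sub["after"] = (sub.period == "after").astype(float)
    sub["lc"] = sub.leaf_clip.astype(float)
    sub["comp"] = sub.complete_recording.astype(float)
    for c in SLOPE_COLS:
        sub["c_" + c] = sub[c] - sub[c].mean()
    keep = ["caller_id", "y", "rank_std"] + SLOPE_COLS[:2] + SLOPE_COLS[3:]
    keep += ["c_" + c for c in SLOPE_COLS]
    return sub[sorted(set(keep))]


R_ORACLE = textwrap.dedent(
    """
    suppressMessages(library(lme4))
    re <- "(1|caller_id) + (0+c_during|caller_id) + (0+c_after|caller_id) +
           (0+c_rank_std|caller_id) + (0+c_lc|caller_id) + (0+c_comp|caller_id)"
    g <- read.csv(commandArgs(TRUE)[1])
    f <- lmer(as.formula(paste("y ~ during + after + rank_std + lc + comp +", re)),
              data=g, REML=FALSE)
    cat("lmm", logLik(f), paste(round(fixef(f), 6), collapse=" "), "\\n")
    p <- read.csv(commandArgs(TRUE)[2])
    pf <- glmer(as.formula(paste("y ~ during + after + rank_std + lc + comp +", re)),
                data=p, family=poisson)
    cat("pois", logLik(pf), paste(round(fixef(pf), 6), collapse=" "), "\\n")
    """
)


def test_fits_match_lme4_oracle(default_calls, tmp_path):
    """lme4 (ML, independent random slopes) agrees with both fitting routes."""
    lmm_frame = _export_model_frame(default_calls, "total_duration_s")
    lmm_frame["y"] = np.sqrt(lmm_frame["y"])
    lmm_path = tmp_path / "lmm.csv"
    lmm_frame.to_csv(lmm_path, index=False)
    pois_frame = _export_model_frame(default_calls, "n_intro_calls")
    pois_path = tmp_path / "pois.csv"
    pois_frame.to_csv(pois_path, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(R_ORACLE)
    out = subprocess.run(
        ["Rscript", str(script), str(lmm_path), str(pois_path)],
        capture_output=True, text=True, timeout=600, check=True,
    ).stdout
    lines = {l.split()[0]: l.split()[1:] for l in out.strip().splitlines() if l}

    by_resp = registry_by_response()
    fit = fit_model(by_resp["total_duration_s"], default_calls)
    r_ll, r_beta = float(lines["lmm"][0]), np.array(lines["lmm"][1:], float)
    assert fit.loglik == pytest.approx(r_ll, abs=2e-3)
    np.testing.assert_allclose(fit.beta, r_beta, atol=2e-3)

    pfit = fit_model(by_resp["n_intro_calls"], default_calls)
    r_ll, r_beta = float(lines["pois"][0]), np.array(lines["pois"][1:], float)
    assert pfit.loglik == pytest.approx(r_ll, abs=5e-3)
    np.testing.assert_allclose(pfit.beta, r_beta, atol=5e-3)


@pytest.fixture(scope="module")
def no_re_calls():
    """Calls simulated with zero random-effect variance (plain GLM regime)."""
    cfg = default_config()
    cfg.re_intercept_sd = {r: 0.0 for r in cfg.re_intercept_sd}
    cfg.re_slope_sd = {r: {p: 0.0 for p in d} for r, d in cfg.re_slope_sd.items()}
    cfg.missing_prob = {r: 0.0 for r in cfg.missing_prob}
    return simulate_call_table(cfg, seed=31)


def _design_frame(calls, response):
    sub = calls[calls[response].notna()]
    X = np.column_stack(
        [
            np.ones(len(sub)),
            (sub.period == "during").astype(float),
            (sub.period == "after").astype(float),
            sub.rank_std.astype(float),
            sub.leaf_clip.astype(float),
            sub.complete_recording.astype(float),
        ]
    )
    return sub, X


def test_lmm_without_group_variance_matches_ols(no_re_calls):
    """With no true caller variance the LMM collapses onto the OLS fit."""
    spec = registry_by_response()["total_duration_s"]
    fit = fit_model(spec, no_re_calls)
    sub, X = _design_frame(no_re_calls, spec.response)
    y = apply_transform(sub[spec.response].to_numpy(float), "sqrt")
    ols = sm.OLS(y, X).fit()
    assert fit.loglik >= ols.llf - 1e-6  # OLS is nested (all ratios zero)
    assert fit.loglik == pytest.approx(ols.llf, abs=0.35)
    np.testing.assert_allclose(fit.beta, ols.params, atol=0.05)


def test_poisson_without_group_variance_matches_glm(no_re_calls):
    spec = registry_by_response()["n_intro_calls"]
    fit = fit_model(spec, no_re_calls)
    sub, X = _design_frame(no_re_calls, spec.response)
    glm = sm.GLM(
        sub[spec.response].to_numpy(float), X, family=sm.families.Poisson()
    ).fit()
    assert fit.loglik >= glm.llf - 1e-6
    assert fit.loglik == pytest.approx(glm.llf, abs=0.35)
    np.testing.assert_allclose(fit.beta, glm.params, atol=0.05)


def test_negbin_without_group_variance_matches_ml_negbin(no_re_calls):
    """Against statsmodels' NB2 ML (which also estimates the shape)."""
    spec = registry_by_response()["n_drum_beats"]
    fit = fit_model(spec, no_re_calls)
    sub, X = _design_frame(no_re_calls, spec.response)
    nb = sm.NegativeBinomial(sub[spec.response].to_numpy(float), X).fit(disp=0)
    # the GLMM nests the GLM (zero variance ratios), so its ML log-likelihood
    # sits at or slightly above the GLM's
    assert nb.llf - 1e-6 <= fit.loglik <= nb.llf + 1.5
    np.testing.assert_allclose(fit.beta, nb.params[:-1], atol=0.15)
    assert fit.nb_theta == pytest.approx(1.0 / nb.params[-1], rel=0.2)


@pytest.mark.parametrize(
    "response", ["total_duration_s", "n_intro_calls", "n_drum_beats"]
)
def test_full_loglik_never_below_null(default_calls, response):
    spec = registry_by_response()[response]
    full = fit_model(spec, default_calls, include_test_predictors=True)
    null = fit_model(spec, default_calls, include_test_predictors=False)
    assert full.loglik >= null.loglik - 1e-6
    assert full.n_obs == null.n_obs


def test_joint_test_dominates_single_drops(default_calls):
    spec = registry_by_response()["total_duration_s"]
    joint = full_null_test(spec, default_calls)
    singles = drop1_tests(spec, default_calls)
    for pred, t in singles.items():
        assert joint.statistic >= t.statistic - 1e-6, pred


def test_p_value_is_chi2_tail():
    t = LikelihoodRatioResult.from_loglik(-100.0, -104.7, df=4)
    assert t.statistic == pytest.approx(9.4)
    assert t.p_value == pytest.approx(chi2.sf(9.4, 4), rel=1e-12)
    # optimizer jitter on nested fits clamps to zero rather than negative
    t0 = LikelihoodRatioResult.from_loglik(-100.0, -100.0 + 1e-9, df=4)
    assert t0.statistic == 0.0 and t0.p_value == 1.0


def test_fit_invariant_to_row_order(default_calls):
    spec = registry_by_response()["total_duration_s"]
    a = fit_model(spec, default_calls)
    shuffled = default_calls.sample(frac=1.0, random_state=11)
    b = fit_model(spec, shuffled)
    assert b.loglik == pytest.approx(a.loglik, abs=1e-6)
    np.testing.assert_allclose(b.beta, a.beta, atol=1e-5)


def test_centered_slope_blocks_sum_to_zero(rng):
    groups = rng.integers(0, 4, size=60)
    raw = {"x1": rng.normal(2.0, 1.0, 60), "dummy": (rng.random(60) < 0.3).astype(float)}
    Z, term_of_col, names = build_random_design(groups, raw)
    assert names == ["intercept", "x1", "dummy"]
    for k in (1, 2):  # each centered-slope block sums to zero exactly
        block = Z[:, term_of_col == k]
        assert block.sum() == pytest.approx(0.0, abs=1e-9)


def test_constant_response_gives_zero_slopes(default_calls):
    spec = registry_by_response()["climax_f0_hz"]
    frozen = default_calls.copy()
    frozen[spec.response] = 800.0
    fit = fit_model(spec, frozen)
    np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-6)
    np.testing.assert_allclose(fit.re_sd, 0.0, atol=1e-6)


def test_wald_ses_are_positive(default_calls):
    for response in ("total_duration_s", "n_buildup_calls"):
        fit = fit_model(registry_by_response()[response], default_calls)
        assert np.all(np.isfinite(fit.se)) and np.all(fit.se > 0)
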