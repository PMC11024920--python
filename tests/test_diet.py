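"""Response construction and quasi-binomial / Gaussian model fitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import fixture_model_frames
from flocknet.diet import (ModelSpec, build_responses, fit_glm,
                           prior_detection_covariate)


def _trial_stream(rows):
    """rows: (tag, day, time, food_type)"""
    df = pd.DataFrame(rows, columns=["tag_id", "day", "time", "food_type"])
    df["site_id"] = "S1"
    df["feeder_id"] = "S1:" + df["food_type"]
    df["period"] = "trial1"
    df["feeder_position"] = "left"
    return df


def irls_oracle(x, successes, totals, tol=1e-12, max_iter=200):
    """Plain textbook IRLS for binomial-logit, independent of the package."""
    x = np.asarray(x, float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = totals * mu * (1 - mu)
        z = eta + (successes - totals * mu) / w
        new = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    mu = 1 / (1 + np.exp(-(x @ beta)))
    pearson = np.sum((successes - totals * mu) ** 2 / (totals * mu * (1 - mu)))
    phi = pearson / (len(successes) - x.shape[1])
    cov = np.linalg.inv(x.T @ ((totals * mu * (1 - mu))[:, None] * x))
    se = np.sqrt(np.diag(cov) * phi)
    return beta, se, phi


def test_build_responses_counts_and_proportion():
    rows = ([("b1", 0, float(t), "novel") for t in range(30)]
            + [("b1", 1, float(t), "familiar") for t in range(70)])
    resp = build_responses(_trial_stream(rows))
    assert resp.loc["b1", "novel_count"] == 30
    assert resp.loc["b1", "familiar_count"] == 70
    prop = resp.loc["b1", "novel_count"] / resp.loc["b1", "n_detections"]
    assert prop == pytest.approx(0.3)


def test_first_arrival_and_zero_latency():
    rows = [("b1", 0, 10.0, "novel"), ("b1", 0, 50.0, "familiar"),
            ("b2", 0, 5.0, "familiar"), ("b2", 0, 30.0, "novel")]
    resp = build_responses(_trial_stream(rows))
    assert bool(resp.loc["b1", "first_arrival_novel"])
    assert resp.loc["b1", "latency_elapsed"] == 0.0
    assert not bool(resp.loc["b2", "first_arrival_novel"])
    assert resp.loc["b2", "latency_elapsed"] == 25.0
    assert resp.loc["b2", "latency_clock"] == 6 * 3600 + 30.0


def test_never_novel_bird_has_missing_latencies():
    rows = [("b1", 0, 10.0, "familiar"), ("b1", 1, 20.0, "familiar")]
    resp = build_responses(_trial_stream(rows))
    assert np.isnan(resp.loc["b1", "latency_clock"])
    assert np.isnan(resp.loc["b1", "latency_elapsed"])
    assert resp.loc["b1", "post_first_novel_count"] == 0
    assert resp.loc["b1", "post_first_familiar_count"] == 0


def test_latency_elapsed_spans_nights_correctly():
    """Only foraging hours count: day remainder + full days + morning."""
    L = 28_800.0
    rows = [("b1", 0, 10_000.0, "familiar"), ("b1", 2, 4_000.0, "novel")]
    resp = build_responses(_trial_stream(rows), day_length_s=L)
    assert resp.loc["b1", "latency_elapsed"] == pytest.approx(
        (L - 10_000.0) + L + 4_000.0)


def test_post_first_counts_strictly_after_first_novel():
    rows = [("b1", 0, 1.0, "familiar"), ("b1", 0, 2.0, "novel"),
            ("b1", 0, 3.0, "familiar"), ("b1", 0, 4.0, "novel")]
    resp = build_responses(_trial_stream(rows))
    assert resp.loc["b1", "post_first_novel_count"] == 1
    assert resp.loc["b1", "post_first_familiar_count"] == 1


def test_unknown_food_type_rejected():
    with pytest.raises(ValueError, match="food_type"):
        build_responses(_trial_stream([("b1", 0, 1.0, "blue")]))


def test_fit_glm_matches_independent_irls_oracle(glm_fixture):
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    fit = fit_glm(responses, metrics, traits, ModelSpec())
    x = fit.design.to_numpy(float)
    succ = fit.endog[:, 0]
    tot = fit.endog.sum(axis=1)
    beta, se, phi = irls_oracle(x, succ, tot)
    assert np.allclose(fit.table["coef"].to_numpy(), beta, atol=1e-6)
    assert np.allclose(fit.table["se"].to_numpy(), se, rtol=1e-6)
    assert fit.phi == pytest.approx(phi, rel=1e-6)
    assert fit.converged


def test_quasibinomial_coefficients_equal_plain_binomial(glm_fixture):
    import statsmodels.api as sm
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    fit = fit_glm(responses, metrics, traits, ModelSpec())
    plain = sm.GLM(fit.endog, fit.design.to_numpy(float),
                   family=sm.families.Binomial()).fit(scale=1.0)
    assert np.max(np.abs(fit.table["coef"].to_numpy() - plain.params)) < 1e-10


def test_balanced_response_gives_zero_slope(glm_fixture):
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    responses = responses.assign(novel_count=50, familiar_count=50,
                                 n_detections=100)
    fit = fit_glm(responses, metrics, traits, ModelSpec())
    assert abs(fit.coef("strength")) < 1e-6


def test_doubling_counts_keeps_coef_shrinks_se(glm_fixture):
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    fit1 = fit_glm(responses, metrics, traits, ModelSpec())
    doubled = responses.assign(
        novel_count=responses["novel_count"] * 2,
        familiar_count=responses["familiar_count"] * 2)
    fit2 = fit_glm(doubled, metrics, traits, ModelSpec())
    assert fit2.coef("strength") == pytest.approx(fit1.coef("strength"),
                                                  abs=1e-8)
    # binomial information doubles; phi is dispersion-confounded, so
    # compare the unscaled (binomial) standard errors
    se1 = fit1.table.set_index("term").loc["strength", "se"] / np.sqrt(fit1.phi)
    se2 = fit2.table.set_index("term").loc["strength", "se"] / np.sqrt(fit2.phi)
    assert se2 < se1


def test_dispersion_near_one_for_binomial_above_one_for_betabinomial(glm_fixture):
    rng = np.random.default_rng(77)
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    logit = -0.5 + 0.4 * metrics["strength"].to_numpy()
    p = 1 / (1 + np.exp(-logit))
    total = 200
    binom = responses.assign(
        novel_count=rng.binomial(total, p), familiar_count=0)
    binom["familiar_count"] = total - binom["novel_count"]
    fit_b = fit_glm(binom, metrics, traits, ModelSpec())
    assert 0.7 <= fit_b.phi <= 1.4
    # beta-binomial: same mean, extra between-bird variance
    rho = 0.05
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    bb = responses.assign(
        novel_count=rng.binomial(total, rng.beta(a, b)), familiar_count=0)
    bb["familiar_count"] = total - bb["novel_count"]
    fit_bb = fit_glm(bb, metrics, traits, ModelSpec())
    assert fit_bb.phi > 1.4


def test_gaussian_family_for_latency(glm_fixture):
    rng = np.random.default_rng(5)
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    responses = responses.assign(
        latency_clock=rng.normal(20_000, 2_000, len(responses)))
    fit = fit_glm(responses, metrics, traits,
                  ModelSpec(response="latency_clock"))
    assert fit.family == "gaussian"
    assert np.isfinite(fit.table["coef"]).all()
    assert fit.phi > 0


def test_incomplete_predictors_are_dropped_not_propagated(glm_fixture):
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    metrics = metrics.copy()
    metrics.iloc[0, metrics.columns.get_loc("strength")] = np.nan
    fit = fit_glm(responses, metrics, traits, ModelSpec())
    assert fit.n_dropped == 1
    assert fit.n_obs == len(responses) - 1


def test_too_few_observations_raise(glm_fixture):
    responses, metrics, traits = fixture_model_frames(glm_fixture)
    with pytest.raises(ValueError, match="observations"):
        fit_glm(responses.iloc[:8], metrics, traits, ModelSpec())


def test_prior_detection_covariate_conserves_stream_length(small_study):
    _, _, stream, _ = small_study
    base = stream[stream["period"] == "baseline"]
    counts = prior_detection_covariate(base)
    assert counts.sum() == len(base)
    assert (counts > 0).all()
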