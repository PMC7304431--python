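"""Binomial GLMs, Gelman standardization and model averaging."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hetfit.hfc_models import (
    all_subsets_average,
    fit_binomial_glm,
    gelman_standardize,
    glm_r2,
    run_reproductive_models,
)


def irls_binomial(X, y, trials, tol=1e-12, max_iter=100):
    """Independent IRLS reference for a logit-link binomial GLM.

    ``y`` are event counts, ``trials`` the per-row trial counts; ``X``
    includes the intercept column.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    ntr = np.asarray(trials, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = ntr * mu * (1 - mu)
        z = eta + (y - ntr * mu) / np.maximum(W, 1e-12)
        XtW = X.T * W
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv((X.T * (ntr * (1 / (1 + np.exp(-(X @ beta)))) *
                                (1 - 1 / (1 + np.exp(-(X @ beta)))))) @ X)
    return beta, np.sqrt(np.diag(cov))


class TestGelman:
    def test_two_point_example(self):
        out = gelman_standardize([0.0, 10.0])
        np.testing.assert_allclose(out, [-0.35355339, 0.35355339], atol=1e-8)

    def test_output_sd_is_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 7, 200)
        out = gelman_standardize(x)
        assert np.mean(out) == pytest.approx(0.0, abs=1e-12)
        assert np.std(out, ddof=1) == pytest.approx(0.5)
        # idempotent up to the factor-2 convention
        assert np.std(gelman_standardize(out), ddof=1) == pytest.approx(0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            gelman_standardize([1.0, 1.0, 1.0])


class TestBinomialGLM:
    def test_intercept_only_pooled_proportion(self):
        df = pd.DataFrame({"y": [1.0] * 10})
        fit = fit_binomial_glm(df, "y", (), trials=4)
        assert fit.params["const"] == pytest.approx(np.log(0.25 / 0.75),
                                                    abs=1e-8)

    def test_intercept_only_bernoulli_half(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 0.0, 1.0]})
        fit = fit_binomial_glm(df, "y", ())
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_irls_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "x1": rng.normal(size=30),
            "x2": rng.normal(size=30),
        })
        eta = 0.3 - 0.8 * df.x1 + 0.5 * df.x2
        df["y"] = rng.binomial(4, 1 / (1 + np.exp(-eta)))
        fit = fit_binomial_glm(df, "y", ("x1", "x2"), trials=4)
        X = np.column_stack([np.ones(30), df.x1, df.x2])
        beta, se = irls_binomial(X, df.y, np.full(30, 4.0))
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(fit.bse.to_numpy(), se, atol=1e-6)

    def test_events_trials_equals_bernoulli_rows(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=25)})
        df["y"] = rng.binomial(4, 0.4, size=25)
        agg = fit_binomial_glm(df, "y", ("x",), trials=4)
        long = pd.DataFrame({
            "x": np.repeat(df.x.to_numpy(), 4),
            "y": np.concatenate(
                [[1.0] * int(y) + [0.0] * (4 - int(y)) for y in df.y]),
        })
        bern = fit_binomial_glm(long, "y", ("x",))
        np.testing.assert_allclose(agg.params.to_numpy(),
                                   bern.params.to_numpy(), atol=1e-8)
        # likelihoods differ exactly by the combinatorial constant
        import math
        const = sum(math.log(math.comb(4, int(y))) for y in df.y)
        assert agg.llf - bern.llf == pytest.approx(const, abs=1e-6)

    def test_aic_identities(self):
        df = pd.DataFrame({"x": np.linspace(-1, 1, 20)})
        df["y"] = (df.x > 0).astype(float) * 3
        fit = fit_binomial_glm(df, "y", ("x",), trials=4)
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.k)
        assert fit.aicc == pytest.approx(
            fit.aic + 2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1))


class TestR2:
    def test_null_model_r2_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = rng.binomial(4, 0.5, size=200)   # x carries no signal
        fit = fit_binomial_glm(df, "y", ("x",), trials=4)
        assert abs(glm_r2(fit, df, "y", trials=4)) < 0.05
        assert abs(glm_r2(fit, df, "y", trials=4, method="kl")) < 0.05

    def test_strong_signal_r2_near_one(self):
        rng = np.random.default_rng(9)
        x = np.linspace(-4, 4, 200)
        df = pd.DataFrame({"x": x})
        df["y"] = rng.binomial(40, 1 / (1 + np.exp(-5 * x)))
        fit = fit_binomial_glm(df, "y", ("x",), trials=40)
        assert glm_r2(fit, df, "y", trials=40) > 0.8


@pytest.fixture(scope="module")
def sim_frame():
    rng = np.random.default_rng(10)
    n = 90
    df = pd.DataFrame({
        "age": rng.choice([1.0, 2, 3, 4], n),
        "ir": rng.normal(0, 0.15, n),
        "year": rng.choice([0.0, 1, 3, 8, 9, 10], n),
    })
    eta = 0.8 - 3.0 * df.ir - 0.3 * df.year
    df["litter_size"] = rng.binomial(4, 1 / (1 + np.exp(-eta)))
    return df.assign(age=gelman_standardize(df.age),
                     ir=gelman_standardize(df.ir),
                     year=gelman_standardize(df.year))


class TestModelAveraging:

    def test_weights_sum_to_one(self, sim_frame):
        avg = all_subsets_average(sim_frame, "litter_size", trials=4)
        assert avg.candidates["weight"].sum() == pytest.approx(1.0)
        assert len(avg.candidates) == 8

    def test_ri_bounds_and_term_in_all_models(self, sim_frame):
        avg = all_subsets_average(sim_frame, "litter_size", trials=4)
        assert ((avg.coef["ri"].dropna() >= 0)
                & (avg.coef["ri"].dropna() <= 1)).all()
        # intercept is in all models: its conditional average equals the
        # full-set weighted mean of per-model intercepts
        w = {row["model"]: row["weight"]
             for _, row in avg.candidates.iterrows()}
        expect = sum(
            w["+".join(s) if s else "(intercept)"] * f.params["const"]
            for s, f in avg.fits.items())
        assert avg.coef.loc["const", "estimate"] == pytest.approx(expect)

    def test_adjusted_se_at_least_conditional_sd(self, sim_frame):
        avg = all_subsets_average(sim_frame, "litter_size", trials=4)
        for term in ("age", "ir", "year"):
            members = [f for s, f in avg.fits.items() if term in s]
            min_se = min(f.bse[term] for f in members)
            assert avg.coef.loc[term, "adj_se"] >= min_se * 0.999

    def test_subset_delta_restricts_candidates(self, sim_frame):
        full = all_subsets_average(sim_frame, "litter_size", trials=4)
        sub = all_subsets_average(sim_frame, "litter_size", trials=4,
                                  subset_delta=2.0)
        assert len(sub.candidates) <= len(full.candidates)
        assert (sub.candidates["delta"] <= 2.0 + 1e-9).all()

    def test_strong_effect_recovered_with_ri_one(self, sim_frame):
        avg = all_subsets_average(sim_frame, "litter_size", trials=4)
        assert avg.coef.loc["ir", "estimate"] < 0
        assert avg.coef.loc["ir", "ri"] > 0.95
        assert avg.r2_global > 0.1


class TestRunReproductiveModels:
    def test_three_model_sets_and_sample_sizes(self, study_dataset):
        from hetfit.mlh import compute_mlh
        mlh_df = compute_mlh(study_dataset.table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_reproductive_models(mlh_df)
        females = mlh_df[(mlh_df.sex == "female")
                         & mlh_df.litter_size.notna()]
        assert set(out) == {"litter_all", "breeding", "litter_breeders"}
        assert out["litter_all"].n == len(females)
        assert out["breeding"].n == len(females)
        assert out["litter_breeders"].n == (females.litter_size >= 1).sum()

    def test_negative_load_detected(self, study_dataset):
        # the generator's default load is strongly negative
        from hetfit.mlh import compute_mlh
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_reproductive_models(compute_mlh(study_dataset.table))
        assert out["litter_all"].coef.loc["ir", "estimate"] < 0
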