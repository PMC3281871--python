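"""Random-intercept model: oracles, Wald calibration, posterior sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from setsim.lmm import (
    ConvergenceError,
    LmmFit,
    ModelFormula,
    fit_lmm,
    sample_posterior,
    wald_p,
    SingularDesignError,
)
from tests.conftest import clustered_frame


def _singleton_frame(rng, n=200, p=3):
    X = rng.standard_normal((n, p))
    y = 0.4 + X @ np.array([0.7, 0.0, 0.2]) + rng.normal(0, 1.0, n)
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(p)])
    df["y"] = y
    df["subject_id"] = np.arange(n)  # one session per subject: no clustering
    return df


def test_beta_equals_ols_without_clustering(rng):
    """With one session per subject the GLS estimate is exactly OLS."""
    df = _singleton_frame(rng)
    fit = fit_lmm(ModelFormula("y", ("x1", "x2", "x3")), df)
    X = np.column_stack([np.ones(len(df)), df[["x1", "x2", "x3"]].to_numpy()])
    ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(fit.beta, ols, atol=1e-6)


def test_agreement_with_statsmodels_mixedlm(lmm_frame):
    import statsmodels.formula.api as smf

    ours = fit_lmm(ModelFormula("y", ("x1", "x2", "x3")), lmm_frame, "ML")
    sm_fit = smf.mixedlm("y ~ x1 + x2 + x3", lmm_frame, groups=lmm_frame["subject_id"]).fit(reml=False)
    np.testing.assert_allclose(ours.beta, sm_fit.fe_params.to_numpy(), atol=1e-4)
    assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-3)
    assert ours.tau2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), abs=1e-3)
    ours_reml = fit_lmm(ModelFormula("y", ("x1", "x2", "x3")), lmm_frame, "REML")
    sm_reml = smf.mixedlm("y ~ x1 + x2 + x3", lmm_frame, groups=lmm_frame["subject_id"]).fit(reml=True)
    assert ours_reml.sigma2 == pytest.approx(float(sm_reml.scale), abs=1e-3)


def test_perfect_fit_hits_sigma_floor(rng):
    df = _singleton_frame(rng)
    df["y"] = df["x1"]
    fit = fit_lmm(ModelFormula("y", ("x1", "x2")), df)
    assert fit.beta[1] == pytest.approx(1.0, abs=1e-6)
    assert fit.beta[2] == pytest.approx(0.0, abs=1e-6)
    assert fit.sigma2 < 1e-10


def test_variance_components_agree_with_moment_estimator():
    """Balanced 50 x 2 design: REML tau^2 tracks the one-way ANOVA
    method-of-moments estimator over 100 replicates."""
    rng = np.random.default_rng(8)
    tau, sigma, n_subj, k = 0.6, 0.8, 50, 2
    ours, mom = [], []
    for _ in range(100):
        groups = np.repeat(np.arange(n_subj), k)
        y = rng.normal(0, tau, n_subj)[groups] + rng.normal(0, sigma, n_subj * k)
        df = pd.DataFrame({"y": y, "subject_id": groups})
        fit = fit_lmm(ModelFormula("y", ()), df, "REML")
        ours.append(fit.tau2)
        gm = df.groupby("subject_id")["y"].mean().to_numpy()
        msb = k * np.var(gm, ddof=1)
        msw = float(df.groupby("subject_id")["y"].var(ddof=1).mean())
        mom.append(max((msb - msw) / k, 0.0))
    assert np.mean(ours) == pytest.approx(np.mean(mom), abs=0.03)
    assert np.mean(ours) == pytest.approx(tau**2, abs=0.08)


def test_wald_p_closed_forms():
    fit = LmmFit(
        names=("Intercept", "a", "b"),
        beta=np.array([0.2, 0.0, 0.392]),
        se=np.array([0.1, 0.15, 0.2]),
        tau2=0.1, sigma2=1.0, loglik=0.0, aic=0.0, n=100, n_groups=50, method="ML",
    )
    assert wald_p(fit, "a") == pytest.approx(1.0)
    assert wald_p(fit, "b") == pytest.approx(0.05, abs=1e-3)  # |z| = 1.96
    with pytest.raises(KeyError):
        wald_p(fit, "missing_term")


def test_wald_p_uniform_under_null():
    rng = np.random.default_rng(4)
    pvals = []
    for _ in range(200):
        df = clustered_frame(rng, n_subj=60, spp=2, beta=(0.0, 0.5, 0.0, 0.0), tau=0.5, sigma=0.8)
        fit = fit_lmm(ModelFormula("y", ("x1", "x2", "x3")), df)
        pvals.append(wald_p(fit, "x3"))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_singular_design_names_columns(lmm_frame):
    df = lmm_frame.copy()
    df["x_dup"] = df["x1"]
    with pytest.raises(SingularDesignError, match="collinear"):
        fit_lmm(ModelFormula("y", ("x1", "x2", "x_dup")), df)


def test_rescaled_fit_invariant_to_affine_raw_units(lmm_frame):
    from setsim.transforms import rescale_for_modeling

    f = ModelFormula("y", ("x1", "x2", "x3"))
    kw = dict(continuous=["x1", "x2", "x3"], binary=[], outcomes=["y"])
    r1, _ = rescale_for_modeling(lmm_frame, **kw)
    shifted = lmm_frame.copy()
    shifted["x1"] = 13.0 * shifted["x1"] - 7.0
    r2, _ = rescale_for_modeling(shifted, **kw)
    np.testing.assert_allclose(fit_lmm(f, r1).beta, fit_lmm(f, r2).beta, atol=1e-8)


def test_aic_prefers_true_predictor_on_average():
    rng = np.random.default_rng(5)
    deltas = []
    for _ in range(20):
        df = clustered_frame(rng, n_subj=80, spp=2, beta=(0.0, 0.5, 0.0, 0.0))
        with_x1 = fit_lmm(ModelFormula("y", ("x1",)), df).aic
        without = fit_lmm(ModelFormula("y", ()), df).aic
        deltas.append(with_x1 - without)
    assert np.mean(deltas) < 0


class TestPosterior:
    def test_mean_close_to_ml_estimate(self, rng):
        df = clustered_frame(rng, n_subj=200, spp=2)
        f = ModelFormula("y", ("x1", "x2", "x3"))
        ml = fit_lmm(f, df)
        post = sample_posterior(f, df, n_draws=2000, seed=3)
        for j, name in enumerate(post.names):
            mcse = post.draws[name].std() / np.sqrt(post.ess[name])
            assert abs(post.draws[name].mean() - ml.beta[j]) < 2 * mcse + 0.02 * ml.se[j]

    def test_same_seed_identical_draws(self, lmm_frame):
        f = ModelFormula("y", ("x1", "x2"))
        a = sample_posterior(f, lmm_frame, n_draws=300, seed=11, burn=100)
        b = sample_posterior(f, lmm_frame, n_draws=300, seed=11, burn=100)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_matches_linear_regression_posterior_without_clustering(self, rng):
        """One row per subject: beta posterior reduces to the standard
        vague-prior Bayesian linear regression (t-like) posterior."""
        df = _singleton_frame(rng, n=300)
        f = ModelFormula("y", ("x1", "x2", "x3"))
        post = sample_posterior(f, df, n_draws=3000, seed=5)
        X = np.column_stack([np.ones(len(df)), df[["x1", "x2", "x3"]].to_numpy()])
        y = df["y"].to_numpy()
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta_hat
        s2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        for j, name in enumerate(post.names):
            assert abs(post.draws[name].mean() - beta_hat[j]) < 0.25 * se[j]
            assert post.draws[name].std() == pytest.approx(se[j], rel=0.2)

    def test_ess_floor_raises(self, lmm_frame):
        f = ModelFormula("y", ("x1",))
        with pytest.raises(ConvergenceError):
            sample_posterior(f, lmm_frame, n_draws=50, burn=10, seed=1, ess_floor=1e9)
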