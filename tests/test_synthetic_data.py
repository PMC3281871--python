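"""Generator: dimensions, determinism, calibration and MAR structure."""

import logging

import numpy as np
import pytest
import statsmodels.api as sm

from setsim import schema
from setsim.config import CohortConfig
from setsim.lmm import ModelFormula, fit_lmm
from setsim.synthetic_data import generate_cohort, impose_missingness


def test_default_pool_dimensions(default_cohort):
    assert default_cohort.n_subjects == 261
    assert default_cohort.n_sessions == 409
    assert default_cohort.n_studies == 23
    default_cohort.validate()


def test_same_seed_is_byte_identical(small_config, small_complete):
    again = generate_cohort(small_config)
    assert small_complete.subjects.to_csv() == again.subjects.to_csv()
    assert small_complete.sessions.to_csv() == again.sessions.to_csv()
    m1 = impose_missingness(small_complete, small_config)
    m2 = impose_missingness(again, small_config)
    assert m1.sessions.to_csv() == m2.sessions.to_csv()
    assert m1.subject_mask.equals(m2.subject_mask)


def test_auxiliary_correlation_matches_configured_value():
    data = generate_cohort(CohortConfig(n_studies=10, n_subjects=500, n_sessions=700, seed=9))
    r = np.corrcoef(data.subjects["pasi"], data.subjects["tas_absorption"])[0, 1]
    assert abs(r - 0.77) < 0.10


def test_predictor_marginals_match_configuration(default_cohort):
    cfg = CohortConfig()
    for name, (mu, sd) in cfg.score_marginals().items():
        x = default_cohort.subjects[name]
        assert abs(x.std(ddof=1) - sd) / sd < 0.10, name
        assert abs(x.mean() - mu) < 0.25 * sd + 0.15, name


def test_outcome_icc_matches_variance_components():
    # with no fixed effects, ICC of the transformed outcome is tau^2/(tau^2+sigma^2);
    # averaged over seeds since a single 200-subject estimate of tau^2 is noisy
    iccs = []
    for seed in range(5):
        cfg = CohortConfig(
            n_studies=10, n_subjects=200, n_sessions=400, true_beta={},
            random_intercept_sd=0.5, residual_sd=0.7, instrument_missing_rates={}, seed=seed,
        )
        data = generate_cohort(cfg)
        frame = data.sessions[["subject_id", "asc_global"]].copy()
        frame["t"] = np.sqrt(frame["asc_global"])
        fit = fit_lmm(ModelFormula("t", ()), frame)
        iccs.append(fit.tau2 / (fit.tau2 + fit.sigma2))
    expected = 0.25 / (0.25 + 0.49)
    assert abs(np.mean(iccs) - expected) < 0.05


def test_naive_flag_never_reverts_and_outcomes_nonnegative(default_cohort):
    sess = default_cohort.sessions.sort_values(["subject_id", "occasion"])
    for _, grp in sess.groupby("subject_id"):
        v = grp["hallucinogen_naive"].to_numpy()
        assert not np.any(np.diff(v) > 0)
    assert (default_cohort.sessions[list(schema.OUTCOMES)].to_numpy() >= 0).all()


def test_block_missingness_is_exactly_study_driven(small_complete, small_config):
    studies = sorted(small_complete.subjects["study_id"].unique())[:4]
    cfg = CohortConfig.from_dict(
        {**small_config.to_dict(), "questionnaire_blocks": {"zkpq": studies}, "instrument_missing_rates": {}}
    )
    out = impose_missingness(small_complete, cfg)
    in_block = out.subjects["study_id"].isin(studies)
    assert out.subject_mask.loc[in_block, "zkpq_n_anx"].all()
    assert not out.subject_mask.loc[~in_block, "zkpq_n_anx"].any()
    assert out.missing_rates()["zkpq_n_anx"] == pytest.approx(in_block.mean())


def test_no_blocks_and_zero_mcar_leaves_mask_all_false(small_complete, small_config):
    cfg = CohortConfig.from_dict({**small_config.to_dict(), "instrument_missing_rates": {}})
    out = impose_missingness(small_complete, cfg)
    assert not out.has_missing


def test_unknown_instrument_in_blocks_is_a_configuration_error(small_complete, small_config):
    cfg = CohortConfig.from_dict(
        {**small_config.to_dict(), "questionnaire_blocks": {"nonexistent_scale": [0]}}
    )
    with pytest.raises(ValueError, match="unknown instrument"):
        impose_missingness(small_complete, cfg)


def test_missingness_is_mar_given_study():
    """Within administering studies, residual (MCAR) missingness of the
    trait scale is unrelated to the outcome in >= 90% of replicates."""
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        cfg = CohortConfig(
            n_studies=6,
            n_subjects=150,
            n_sessions=220,
            instrument_missing_rates={"tas": 0.3},
            extra_mcar_rate=0.3,
            mcar_columns=("tas_absorption",),
            seed=1000 + rep,
        )
        data = impose_missingness(generate_cohort(cfg), cfg)
        subj = data.subjects.set_index("subject_id")
        outcome = data.sessions.groupby("subject_id")["asc_global"].mean()
        block_missing = subj.groupby("study_id")["tas_absorption"].transform(lambda s: s.isna().all())
        admin = ~block_missing
        y = subj.loc[admin, "tas_absorption"].isna().astype(float)
        x = sm.add_constant(np.sqrt(outcome[admin.index[admin]]))
        res = sm.Logit(y.to_numpy(), x.to_numpy()).fit(disp=0)
        hits += int(res.pvalues[1] > 0.05)
    assert hits >= 0.9 * n_rep


def test_invalid_configurations_are_rejected():
    with pytest.raises(ValueError, match="115"):
        CohortConfig(dose_levels=(50.0, 170.0), dose_probs=(0.5, 0.5))
    with pytest.raises(ValueError, match="residual_sd"):
        CohortConfig(residual_sd=0.0)
    with pytest.raises(ValueError, match="unknown predictor"):
        CohortConfig(true_beta={"not_a_predictor": 0.5})
    with pytest.raises(ValueError, match=r"\(-1, 1\)"):
        CohortConfig(aux_correlations={("pasi", "tas_absorption"): 1.0})


def test_out_of_range_inverse_values_are_clipped_and_logged(caplog):
    # a large negative intercept on the sqrt scale forces clipping at zero
    cfg = CohortConfig(
        n_studies=4, n_subjects=60, n_sessions=100,
        outcome_intercepts={o: -1.0 for o in schema.OUTCOMES},
        instrument_missing_rates={}, seed=3,
    )
    with caplog.at_level(logging.INFO, logger="setsim.synthetic_data"):
        data = generate_cohort(cfg)
    assert (data.sessions["asc_global"] == 0).any()
    assert any("clipped" in rec.message for rec in caplog.records)
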