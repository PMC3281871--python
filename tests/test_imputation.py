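"""Chained-equation imputation: screening, proper MI behaviour, VIF."""

import numpy as np
import pandas as pd
import pytest

from setsim import schema
from setsim.config import CohortConfig
from setsim.imputation import (
    ImputationPlan,
    build_predictor_sets,
    diagnose_chains,
    fcs_impute,
    vif_screen,
)
from setsim.synthetic_data import generate_cohort, impose_missingness


@pytest.fixture(scope="module")
def plan(small_missing):
    return build_predictor_sets(small_missing, m=4, n_iter=6, seed=7)


@pytest.fixture(scope="module")
def stack(small_missing, plan):
    return fcs_impute(small_missing, plan)


class TestPredictorScreen:
    def test_threshold_keeps_only_correlated_candidates(self, small_missing):
        plan = build_predictor_sets(small_missing, threshold=0.5, m=2, seed=0)
        # at a strict threshold, the trait scale keeps its strong auxiliary
        assert "pasi" in plan.predictors["tas_absorption"]
        # fallback guarantees non-empty sets everywhere
        assert all(len(p) > 0 for p in plan.predictors.values())

    def test_auxiliaries_always_eligible(self, plan):
        assert "pasi" in plan.predictors["tas_absorption"]
        assert "fpi_emotional_lability" in plan.predictors["zkpq_n_anx"]

    def test_zero_threshold_includes_everything_correlatable(self, small_missing):
        plan0 = build_predictor_sets(small_missing, threshold=0.0, m=2, seed=0)
        sizes = plan0.set_sizes()
        # every candidate with a defined pairwise correlation is included
        assert sizes["tas_absorption"] >= 30

    def test_set_sizes_in_sanity_band(self, plan):
        sizes = plan.set_sizes()
        assert ((sizes >= 1) & (sizes <= 45)).all()

    def test_methods_match_variable_kinds(self, plan):
        assert plan.methods["tas_absorption"] == "pmm"
        for var, meth in plan.methods.items():
            kind = schema.SCHEMA[var].kind
            assert {"continuous": "pmm", "binary": "logistic", "ordinal": "proportional_odds"}[kind] == meth

    def test_plan_invariants_enforced(self):
        with pytest.raises(ValueError, match="m must be"):
            ImputationPlan(methods={}, predictors={}, levels={}, m=1)
        with pytest.raises(ValueError, match="does not match kind"):
            ImputationPlan(
                methods={"tas_absorption": "logistic"},
                predictors={"tas_absorption": ("age",)},
                levels={"tas_absorption": "subject"},
            )


class TestFcsImpute:
    def test_no_missing_data_gives_identical_copies(self, small_complete):
        plan = ImputationPlan(methods={}, predictors={}, levels={}, m=3)
        out = fcs_impute(small_complete, plan)
        assert out.m == 3
        for ds in out.datasets:
            pd.testing.assert_frame_equal(ds.subjects, small_complete.subjects)
        assert out.traces == {}

    def test_observed_cells_never_altered(self, small_missing, stack):
        for ds in stack.datasets:
            for col in schema.IMPUTABLE_SUBJECT:
                obs = ~small_missing.subject_mask[col]
                np.testing.assert_array_equal(
                    ds.subjects.loc[obs, col].to_numpy(), small_missing.subjects.loc[obs, col].to_numpy()
                )

    def test_nothing_left_missing_and_subject_level_constant(self, stack):
        for ds in stack.datasets:
            assert not ds.subjects[list(schema.IMPUTABLE_SUBJECT)].isna().any().any()
            assert not ds.sessions[list(schema.IMPUTABLE_SESSION)].isna().any().any()
            merged = ds.merged()
            assert (merged.groupby("subject_id")["tas_absorption"].nunique() == 1).all()

    def test_pmm_imputes_only_observed_values(self, small_missing, stack):
        col = "tas_absorption"
        observed = set(small_missing.subjects.loc[~small_missing.subject_mask[col], col])
        for ds in stack.datasets:
            imputed = ds.subjects.loc[small_missing.subject_mask[col], col]
            assert set(imputed) <= observed

    def test_trace_shapes(self, stack, plan):
        for var, tr in stack.traces.items():
            assert tr.shape == (plan.m, plan.n_iter, 2)
            assert np.isfinite(tr).all()

    def test_mcar_mean_recovered_within_tenth_sd(self):
        cfg = CohortConfig(
            n_studies=8, n_subjects=200, n_sessions=400,
            instrument_missing_rates={}, extra_mcar_rate=0.30,
            mcar_columns=("tas_absorption",), seed=31,
        )
        complete = generate_cohort(cfg)
        data = impose_missingness(complete, cfg)
        plan = build_predictor_sets(data, m=10, n_iter=6, seed=2)
        out = fcs_impute(data, plan)
        pooled_mean = np.mean([ds.subjects["tas_absorption"].mean() for ds in out.datasets])
        truth = complete.subjects["tas_absorption"]
        assert abs(pooled_mean - truth.mean()) < 0.1 * truth.std(ddof=1)


class TestDiagnostics:
    def test_empty_report_without_missing_data(self, small_complete):
        plan = ImputationPlan(methods={}, predictors={}, levels={}, m=2)
        diag = diagnose_chains(fcs_impute(small_complete, plan))
        assert diag.empty and diag.flagged == []

    def test_well_specified_chains_mix(self, small_missing):
        # enough chains that the between-chain variance is not itself noise
        plan = build_predictor_sets(small_missing, m=8, n_iter=20, seed=3)
        diag = diagnose_chains(fcs_impute(small_missing, plan))
        assert (diag.table["ratio"] < 1.2).all()

    def test_informative_imputation_beats_marginal_fallback(self):
        """Breaking the auxiliary dependence biases imputed values; keeping
        it recovers the pre-deletion mean of the missing stratum."""
        cfg = CohortConfig(
            n_studies=6, n_subjects=240, n_sessions=300,
            instrument_missing_rates={"tas": 0.5}, seed=17,
        )
        complete = generate_cohort(cfg)
        data = impose_missingness(complete, cfg)
        mask = data.subject_mask["tas_absorption"].to_numpy()
        truth = complete.subjects.loc[mask, "tas_absorption"].to_numpy()
        good = build_predictor_sets(data, m=4, n_iter=6, seed=5)
        bad_predictors = {**good.predictors, "tas_absorption": ("bmi",)}  # aux excluded
        bad = ImputationPlan(
            methods=good.methods, predictors=bad_predictors, levels=good.levels,
            m=4, n_iter=6, seed=5,
        )
        err_good = err_bad = 0.0
        for plan in (good, bad):
            out = fcs_impute(data, plan)
            est = np.mean([ds.subjects.loc[mask, "tas_absorption"].mean() for ds in out.datasets])
            err = abs(est - truth.mean())
            if plan is good:
                err_good = err
            else:
                err_bad = err
        assert err_good <= err_bad


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self, rng):
        n = 4000
        frame = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
        vif = vif_screen([frame], ["a", "b", "c"])
        assert np.allclose(vif["max_vif"], 1.0, atol=0.02)
        assert not vif["flag"].any()

    def test_correlated_pair_matches_closed_form(self, rng):
        n = 20000
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        frame = pd.DataFrame({"a": a, "b": b, "c": rng.standard_normal(n)})
        vif = vif_screen([frame], ["a", "b", "c"])
        assert vif.loc["a", "max_vif"] == pytest.approx(1 / (1 - 0.64), rel=0.05)
        assert vif.loc["b", "max_vif"] == pytest.approx(2.78, rel=0.05)

    def test_duplicated_predictor_reports_infinite_vif(self, rng):
        a = rng.standard_normal(500)
        frame = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(500)})
        vif = vif_screen([frame], ["a", "b", "c"])
        assert np.isinf(vif.loc["a", "max_vif"])
        assert vif.loc["a", "flag"]
        assert vif.loc["a", "collinear_with"] == "b"

    def test_default_cohort_predictors_pass_the_screen(self, stack):
        vif = vif_screen(stack, schema.MODEL_TERMS)
        assert (vif["max_vif"] < 3.0).all()
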