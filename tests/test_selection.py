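"""Bootstrap backward-elimination selection and the interaction screen."""

import numpy as np
import pandas as pd
import pytest

from setsim.lmm import ModelFormula, fit_lmm, wald_p
from setsim.selection import (
    aic_alpha_equivalence,
    backward_eliminate,
    bootstrap_select,
    screen_interactions,
    two_step_select,
)
from tests.conftest import clustered_frame


class TestAicAlphaEquivalence:
    def test_default_penalty_gives_0157(self):
        assert aic_alpha_equivalence() == pytest.approx(0.157, abs=5e-4)

    def test_five_percent_critical_value(self):
        assert aic_alpha_equivalence(3.841) == pytest.approx(0.050, abs=5e-4)

    def test_explicit_penalty_two_matches_default(self):
        assert aic_alpha_equivalence(2.0) == aic_alpha_equivalence()


class TestBackwardEliminate:
    def test_full_model_kept_when_all_significant(self, rng):
        df = clustered_frame(rng, n_subj=200, spp=2, beta=(0.0, 0.6, 0.5, 0.4))
        f = ModelFormula("y", ("x1", "x2", "x3"))
        assert backward_eliminate(f, df).predictors == f.predictors

    def test_pure_noise_predictor_usually_removed(self):
        rng = np.random.default_rng(12)
        removed = 0
        n_rep = 200
        for _ in range(n_rep):
            df = clustered_frame(rng, n_subj=100, spp=2, beta=(0.0, 0.6, 0.0, 0.0))
            reduced = backward_eliminate(ModelFormula("y", ("x1", "x3")), df)
            removed += "x3" not in reduced.predictors
        assert removed / n_rep >= 0.80

    def test_drop_sequence_matches_manual_refit_oracle(self, rng):
        df = clustered_frame(rng, n_subj=120, spp=2, beta=(0.0, 0.5, 0.12, 0.0))
        f = ModelFormula("y", ("x1", "x2", "x3"))
        reduced, seq = backward_eliminate(f, df, return_sequence=True)
        # independent oracle: refit after each single drop using the public API
        current = f
        oracle_seq = []
        while True:
            fit = fit_lmm(current, df)
            pv = {t: wald_p(fit, t) for t in current.predictors}
            worst = max(pv, key=lambda t: (pv[t], current.predictors.index(t)))
            if pv[worst] <= 0.157:
                break
            oracle_seq.append(worst)
            current = current.drop(worst)
        assert seq == oracle_seq
        assert reduced.predictors == current.predictors

    def test_locked_terms_are_never_dropped(self, rng):
        df = clustered_frame(rng, n_subj=100, spp=2, beta=(0.0, 0.5, 0.0, 0.0))
        f = ModelFormula("y", ("x1", "x2", "x3"), locked=("x3",))
        reduced = backward_eliminate(f, df, alpha=1e-6)
        assert "x3" in reduced.predictors


@pytest.fixture(scope="module")
def frames():
    rng = np.random.default_rng(3)
    return [clustered_frame(rng, n_subj=150, spp=2, beta=(0.0, 0.55, 0.4, 0.0)) for _ in range(2)]


class TestBootstrapSelect:
    def test_degenerate_single_sample_equals_one_elimination(self, frames):
        full = ModelFormula("y", ("x1", "x2", "x3"))
        res = bootstrap_select(frames[:1], full, B=1, step=1, seed=5)
        rng = np.random.default_rng([5, 0, 0])
        rows = rng.integers(0, len(frames[0]), size=len(frames[0]))
        resampled = frames[0].iloc[rows].reset_index(drop=True)
        direct = backward_eliminate(full, resampled)
        for term in full.predictors:
            assert res.step1_frequencies[term] == float(term in direct.predictors)

    def test_cutoff_extremes(self, frames):
        full = ModelFormula("y", ("x1", "x2", "x3"))
        all_in = bootstrap_select(frames, full, B=10, cutoff=0.0, step=1, seed=1)
        assert all_in.retained == full.predictors
        none = bootstrap_select(frames, full, B=10, cutoff=1.01, step=1, seed=1)
        assert none.retained == ()

    def test_two_step_modal_model_within_retained_set(self, frames):
        full = ModelFormula("y", ("x1", "x2", "x3"))
        res = two_step_select(frames, full, B=30, seed=9)
        assert res.most_stable_model is not None
        assert set(res.most_stable_model.predictors) <= set(res.retained)
        assert ((res.step1_frequencies >= 0) & (res.step1_frequencies <= 1)).all()
        assert abs(sum(res.step2_model_frequencies.values()) - 1.0) < 1e-12
        # strong effects survive both steps
        assert {"x1", "x2"} <= set(res.most_stable_model.predictors)

    def test_reproducible_from_seed(self, frames):
        full = ModelFormula("y", ("x1", "x2", "x3"))
        a = bootstrap_select(frames, full, B=20, step=1, seed=4)
        b = bootstrap_select(frames, full, B=20, step=1, seed=4)
        pd.testing.assert_series_equal(a.step1_frequencies, b.step1_frequencies)


class TestInteractionScreen:
    def _frames(self, dose_pet_gap=False):
        rng = np.random.default_rng(21)
        n_subj, spp = 150, 2
        n = n_subj * spp
        groups = np.repeat(np.arange(n_subj), spp)
        dose = rng.choice([-1.0, -0.3, 0.4, 1.0], size=n)
        pet = (rng.random(n) < 0.15).astype(float)
        if dose_pet_gap:  # dose nearly constant within the PET stratum
            dose[pet == 1] = 0.4
        x = rng.standard_normal(n)
        y = 0.7 * dose + 0.3 * x + rng.normal(0, 0.4, n_subj)[groups] + rng.normal(0, 0.8, n)
        return [pd.DataFrame({"y": y, "dose": dose, "pet": pet, "x": x, "subject_id": groups})]

    def test_null_interactions_not_flagged_and_never_added(self):
        frames = self._frames()
        model = ModelFormula("y", ("dose", "pet", "x"))
        tab = screen_interactions(frames, model, base="dose", seed=2)
        assert set(tab.index) == {"dose:pet", "dose:x"}
        assert model.predictors == ("dose", "pet", "x")  # unchanged
        assert (tab["p"] > 0.001).all()

    def test_low_dose_variability_within_stratum_warns(self, caplog):
        frames = self._frames(dose_pet_gap=True)
        model = ModelFormula("y", ("dose", "pet", "x"))
        import logging

        with caplog.at_level(logging.WARNING, logger="setsim.selection"):
            tab = screen_interactions(frames, model, base="dose", seed=2)
        assert bool(tab.loc["dose:pet", "low_base_variability"])
        assert any("dose variability" in r.message for r in caplog.records)

    def test_collinear_interaction_reported_untestable(self):
        frames = self._frames()
        frames[0]["allone"] = 1.0  # dose:allone coincides with dose itself
        model = ModelFormula("y", ("dose", "allone", "x"))
        tab = screen_interactions(frames, model, base="dose", candidates=("allone",), seed=2)
        assert bool(tab.loc["dose:allone", "untestable"])

    def test_real_interaction_detected(self):
        rng = np.random.default_rng(33)
        n = 400
        groups = np.arange(n)
        dose = rng.standard_normal(n)
        z = (rng.random(n) < 0.5).astype(float)
        y = 0.5 * dose + 0.3 * z + 0.6 * dose * z + rng.normal(0, 0.7, n)
        frames = [pd.DataFrame({"y": y, "dose": dose, "z": z, "subject_id": groups})]
        tab = screen_interactions(frames, ModelFormula("y", ("dose", "z")), base="dose", seed=3)
        assert tab.loc["dose:z", "p"] < 0.01
        assert tab.loc["dose:z", "flag"] == "**"


def test_subject_level_resampling_mode(frames):
    """The cluster-bootstrap flag draws whole subjects and still returns a
    well-formed frequency table."""
    full = ModelFormula("y", ("x1", "x2", "x3"))
    res = bootstrap_select(frames, full, B=10, step=1, seed=6, resample="subjects")
    assert ((res.step1_frequencies >= 0) & (res.step1_frequencies <= 1)).all()
    assert res.step1_frequencies["x1"] >= 0.9  # strong effect survives
    with pytest.raises(ValueError, match="resample"):
        bootstrap_select(frames, full, B=1, resample="bogus")
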