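"""Cohort-generator configuration.

Defaults are calibrated to the pooled multi-study psilocybin cohort this
package emulates: 23 studies, 261 subjects, 409 sessions, the published
dose/assessment-time category frequencies, subject descriptive statistics,
and questionnaire missing-data rates driven by which instruments each study
administered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import schema

__all__ = ["CohortConfig", "allocate_subjects", "allocate_sessions"]


def _default_true_beta() -> dict[str, float]:
    # Generating hierarchy: dose dominates, then one pre-drug state scale and
    # one personality trait; everything else is a true zero.
    return {"dose": 0.8, "ewl_emo_excitability": 0.4, "tas_absorption": 0.4}


def _default_outcome_transforms() -> dict[str, str]:
    tf = {o: "sqrt" for o in schema.OUTCOMES}
    for o in ("ded", "spiritual", "insight", "disembodiment", "synesthesia"):
        tf[o] = "log"
    tf["anxiety"] = "neg_inv_sqrt"
    return tf


def _default_aux_correlations() -> dict[tuple[str, str], float]:
    # The imagination scale correlates 0.77 with trait Absorption; the three
    # auxiliary personality scales are convergent measures of their partners.
    return {
        ("pasi", "tas_absorption"): 0.77,
        ("fpi_extraversion", "zkpq_sociability"): 0.6,
        ("fpi_emotional_lability", "zkpq_n_anx"): 0.6,
        ("fpi_aggressiveness", "zkpq_agg_host"): 0.6,
    }


def _default_predictor_correlations() -> dict[tuple[str, str], float]:
    # Pre-drug Emotional Excitability and Anxiety-Depressiveness correlate 0.5;
    # all other cross-correlations default to zero.
    return {("ewl_emo_excitability", "ewl_anx_depressiveness"): 0.5}


def _default_missing_rates() -> dict[str, float]:
    # Target per-instrument missing fractions (share of subjects/sessions in
    # studies that did not administer the instrument).
    return {
        "bmi": 0.25,
        "smoking": 0.24,
        "alcohol": 0.23,
        "thc": 0.16,
        "naive": 0.15,
        "zkpq": 0.52,
        "fpi": 0.41,
        "tas": 0.72,
        "pasi": 0.59,
        "scl": 0.31,
        "ewl": 0.55,
    }


# Continuous score marginals: mean, SD (normed scores for personality and
# distress scales, raw units for age/BMI).
_SCORE_MARGINALS = {
    "age": (27.8, 6.0),
    "bmi": (22.2, 2.3),
    "zkpq_imp_ss": (0.4, 0.8),
    "zkpq_n_anx": (-0.9, 0.7),
    "zkpq_agg_host": (-0.6, 0.9),
    "zkpq_act": (0.0, 0.9),
    "zkpq_sociability": (-0.1, 0.9),
    "tas_absorption": (-0.8, 1.2),
    "scl_gsi": (-0.3, 0.9),
    "fpi_extraversion": (0.0, 1.0),
    "fpi_emotional_lability": (0.0, 1.0),
    "fpi_aggressiveness": (0.0, 1.0),
    "pasi": (0.0, 1.0),
}

_BINARY_MARGINALS = {"female": 0.38, "daily_smoker": 0.30, "alcohol": 0.45, "hallucinogen_naive": 0.59}

_EDUCATION_PROBS = (0.09, 0.56, 0.35)
_THC_PROBS = (0.16, 0.50, 0.34)

#: Default generating intercepts on the transformed outcome scale, per
#: named transform.  Chosen so the implied raw visual-analogue scores sit in
#: a plausible range (sqrt: mean ~16; log: ~7; -1/sqrt: ~0.4).
_TRANSFORM_INTERCEPTS = {"sqrt": 4.0, "log": 2.0, "neg_inv_sqrt": -1.5, "identity": 10.0}


@dataclass
class CohortConfig:
    """Generating conditions for a pooled multi-study cohort."""

    n_studies: int = 23
    n_subjects: int = 261
    n_sessions: int = 409
    subjects_per_study: Sequence[int] | None = None
    sessions_per_subject: Sequence[int] | None = None

    # Session design: dose categories (µg/kg, representative values) and
    # assessment-time categories (minutes after intake) with their observed
    # frequencies; sessions in PET studies carry the PET flag.
    dose_levels: Sequence[float] = (120.0, 170.0, 220.0, 260.0, 315.0)
    dose_probs: Sequence[float] = (0.23, 0.09, 0.20, 0.38, 0.10)
    time_levels_min: Sequence[float] = (75.0, 135.0, 230.0, 480.0, 1440.0)
    time_probs: Sequence[float] = (0.23, 0.39, 0.23, 0.13, 0.02)
    pet_study_fraction: float = 0.12  # target share of sessions in PET studies

    # Outcome-generating mixed model (on the transformed scale, effects in
    # 2-SD standardized predictor units).
    true_beta: Mapping[str, float] = field(default_factory=_default_true_beta)
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.7
    outcome_transforms: Mapping[str, str] = field(default_factory=_default_outcome_transforms)
    outcome_intercepts: Mapping[str, float] | None = None

    aux_correlations: Mapping[tuple[str, str], float] = field(default_factory=_default_aux_correlations)
    predictor_correlations: Mapping[tuple[str, str], float] = field(default_factory=_default_predictor_correlations)

    # Missingness: either explicit blocks (instrument -> iterable of study
    # ids that did NOT administer it) or target rates from which blocks are
    # derived; plus an optional extra cell-wise MCAR rate.
    questionnaire_blocks: Mapping[str, Sequence[int]] | None = None
    instrument_missing_rates: Mapping[str, float] = field(default_factory=_default_missing_rates)
    extra_mcar_rate: float = 0.0
    mcar_columns: Sequence[str] | None = None

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd <= 0:
            raise ValueError("random_intercept_sd must be >= 0 and residual_sd > 0")
        if min(self.dose_levels) < 115:
            raise ValueError("dose levels below the 115 µg/kg analysis floor")
        if not np.isclose(sum(self.dose_probs), 1.0) or not np.isclose(sum(self.time_probs), 1.0):
            raise ValueError("dose_probs and time_probs must sum to 1")
        for name in self.true_beta:
            if name not in schema.MODEL_TERMS:
                raise ValueError(f"true_beta names unknown predictor {name!r}")
        for pair, r in list(self.aux_correlations.items()) + list(self.predictor_correlations.items()):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation for {pair} outside (-1, 1)")
        for o, t in self.outcome_transforms.items():
            if o not in schema.OUTCOMES:
                raise ValueError(f"unknown outcome {o!r} in outcome_transforms")
            if t not in ("log", "sqrt", "neg_inv_sqrt", "identity"):
                raise ValueError(f"unknown transform {t!r} for outcome {o!r}")
        if not 0.0 <= self.extra_mcar_rate < 1.0:
            raise ValueError("extra_mcar_rate must be in [0, 1)")
        if self.subjects_per_study is not None and sum(self.subjects_per_study) != self.n_subjects:
            raise ValueError("subjects_per_study must sum to n_subjects")
        if self.sessions_per_subject is not None and sum(self.sessions_per_subject) != self.n_sessions:
            raise ValueError("sessions_per_subject must sum to n_sessions")
        if self.n_sessions < self.n_subjects:
            raise ValueError("need at least one session per subject")

    # -- derived generating quantities ---------------------------------
    def score_marginals(self) -> dict[str, tuple[float, float]]:
        return dict(_SCORE_MARGINALS)

    def binary_marginals(self) -> dict[str, float]:
        return dict(_BINARY_MARGINALS)

    def education_probs(self) -> tuple[float, ...]:
        return _EDUCATION_PROBS

    def thc_probs(self) -> tuple[float, ...]:
        return _THC_PROBS

    def intercept_for(self, outcome: str) -> float:
        if self.outcome_intercepts and outcome in self.outcome_intercepts:
            return float(self.outcome_intercepts[outcome])
        return _TRANSFORM_INTERCEPTS[self.outcome_transforms[outcome]]

    def dose_moments(self) -> tuple[float, float]:
        """Generating mean and SD of the dose distribution (for 2-SD scaling)."""
        p = np.asarray(self.dose_probs)
        x = np.asarray(self.dose_levels, dtype=float)
        mu = float(p @ x)
        sd = float(np.sqrt(p @ (x - mu) ** 2))
        return mu, sd

    def time_moments(self) -> tuple[float, float]:
        p = np.asarray(self.time_probs)
        x = np.log(np.asarray(self.time_levels_min, dtype=float))
        mu = float(p @ x)
        sd = float(np.sqrt(p @ (x - mu) ** 2))
        return mu, sd

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["aux_correlations"] = {f"{a}|{b}": r for (a, b), r in self.aux_correlations.items()}
        d["predictor_correlations"] = {f"{a}|{b}": r for (a, b), r in self.predictor_correlations.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("aux_correlations", "predictor_correlations"):
            if key in d and d[key] and isinstance(next(iter(d[key])), str):
                d[key] = {tuple(k.split("|")): v for k, v in d[key].items()}
        if "true_beta" in d and d["true_beta"] is not None:
            d["true_beta"] = dict(d["true_beta"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


def allocate_subjects(config: CohortConfig) -> np.ndarray:
    """Study id per subject (near-even deterministic split unless given)."""
    if config.subjects_per_study is not None:
        counts = np.asarray(config.subjects_per_study, dtype=int)
    else:
        base = config.n_subjects // config.n_studies
        counts = np.full(config.n_studies, base, dtype=int)
        counts[: config.n_subjects - base * config.n_studies] += 1
    return np.repeat(np.arange(len(counts)), counts)


def allocate_sessions(config: CohortConfig) -> np.ndarray:
    """Number of sessions per subject.

    Deterministic: every subject gets one session, the remainder is spread
    round-robin (cap 5 per subject, matching the 2-5 session designs).
    """
    if config.sessions_per_subject is not None:
        return np.asarray(config.sessions_per_subject, dtype=int)
    counts = np.ones(config.n_subjects, dtype=int)
    extra = config.n_sessions - config.n_subjects
    i = 0
    while extra > 0:
        if counts[i % config.n_subjects] < 5:
            counts[i % config.n_subjects] += 1
            extra -= 1
        i += 1
    return counts
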