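"""Variable schema for the pooled multi-study cohort.

The data model is a pair of linked tables: one row per subject (screening
variables: demographics, drug-use categories, personality and distress
scores) and one row per drug session (design variables, pre-drug mood state
and the outcome scales).  Every variable carries metadata used throughout
the pipeline: at which level it lives, its statistical kind (which decides
the imputation model), the instrument it belongs to (which drives
study-block missingness) and its role in the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VarInfo",
    "SCHEMA",
    "SUBJECT_COLUMNS",
    "SESSION_COLUMNS",
    "OUTCOMES",
    "MAIN_SCALES",
    "SUBSCALES",
    "PREDICTORS",
    "MODEL_TERMS",
    "AUX_LINKS",
    "IMPUTABLE_SUBJECT",
    "IMPUTABLE_SESSION",
    "instrument_columns",
    "EDUCATION_LEVELS",
    "THC_LEVELS",
]


@dataclass(frozen=True)
class VarInfo:
    name: str
    level: str        # "subject" | "session"
    kind: str         # "continuous" | "binary" | "ordinal" | "id" | "design"
    instrument: str   # block-missingness unit; "core" is always administered
    role: str         # "predictor" | "auxiliary" | "outcome" | "id" | "design"


EDUCATION_LEVELS = ("high_school", "student", "graduate")
THC_LEVELS = ("never", "rarely", "sometimes")

# Outcome scales: four main altered-state dimensions plus eleven lower-order
# factors, all scored on non-negative visual-analogue metrics.
MAIN_SCALES = ("asc_global", "obn", "ded", "vrs")
SUBSCALES = (
    "unity",
    "spiritual",
    "bliss",
    "insight",
    "disembodiment",
    "impaired_control",
    "anxiety",
    "complex_imagery",
    "elementary_imagery",
    "synesthesia",
    "changed_meaning",
)
OUTCOMES = MAIN_SCALES + SUBSCALES

_SUBJECT_VARS = [
    VarInfo("subject_id", "subject", "id", "core", "id"),
    VarInfo("study_id", "subject", "id", "core", "id"),
    VarInfo("age", "subject", "continuous", "core", "predictor"),
    VarInfo("female", "subject", "binary", "core", "predictor"),
    VarInfo("education", "subject", "ordinal", "core", "predictor"),
    VarInfo("bmi", "subject", "continuous", "bmi", "predictor"),
    VarInfo("daily_smoker", "subject", "binary", "smoking", "predictor"),
    VarInfo("alcohol", "subject", "binary", "alcohol", "predictor"),
    VarInfo("thc", "subject", "ordinal", "thc", "predictor"),
    VarInfo("zkpq_imp_ss", "subject", "continuous", "zkpq", "predictor"),
    VarInfo("zkpq_n_anx", "subject", "continuous", "zkpq", "predictor"),
    VarInfo("zkpq_agg_host", "subject", "continuous", "zkpq", "predictor"),
    VarInfo("zkpq_act", "subject", "continuous", "zkpq", "predictor"),
    VarInfo("zkpq_sociability", "subject", "continuous", "zkpq", "predictor"),
    VarInfo("tas_absorption", "subject", "continuous", "tas", "predictor"),
    VarInfo("scl_gsi", "subject", "continuous", "scl", "predictor"),
    # Auxiliary scales: used only to improve imputation of their partners.
    VarInfo("fpi_extraversion", "subject", "continuous", "fpi", "auxiliary"),
    VarInfo("fpi_emotional_lability", "subject", "continuous", "fpi", "auxiliary"),
    VarInfo("fpi_aggressiveness", "subject", "continuous", "fpi", "auxiliary"),
    VarInfo("pasi", "subject", "continuous", "pasi", "auxiliary"),
]

_EWL_SCALES = (
    "ewl_performance_activity",
    "ewl_inactivation",
    "ewl_extraversion",
    "ewl_wellbeing",
    "ewl_emo_excitability",
    "ewl_anx_depressiveness",
)

_SESSION_VARS = (
    [
        VarInfo("session_id", "session", "id", "core", "id"),
        VarInfo("subject_id", "session", "id", "core", "id"),
        VarInfo("study_id", "session", "id", "core", "id"),
        VarInfo("occasion", "session", "id", "core", "id"),
        VarInfo("dose", "session", "continuous", "core", "design"),
        VarInfo("pet", "session", "binary", "core", "design"),
        VarInfo("time_min", "session", "continuous", "core", "id"),
        VarInfo("log_time", "session", "continuous", "core", "design"),
        VarInfo("hallucinogen_naive", "session", "binary", "naive", "predictor"),
    ]
    + [VarInfo(s, "session", "continuous", "ewl", "predictor") for s in _EWL_SCALES]
    + [VarInfo(o, "session", "continuous", "oav", "outcome") for o in OUTCOMES]
)

SCHEMA: dict[str, VarInfo] = {v.name: v for v in _SUBJECT_VARS + _SESSION_VARS}

SUBJECT_COLUMNS = tuple(v.name for v in _SUBJECT_VARS)
SESSION_COLUMNS = tuple(v.name for v in _SESSION_VARS)

EWL_SCALES = _EWL_SCALES

#: Subject- and session-level predictor/auxiliary columns eligible for
#: study-block missingness and imputation (instruments other than "core"
#: and the design variables).
IMPUTABLE_SUBJECT = tuple(
    v.name for v in _SUBJECT_VARS if v.instrument not in ("core",) and v.role in ("predictor", "auxiliary")
)
IMPUTABLE_SESSION = tuple(
    v.name for v in _SESSION_VARS if v.instrument not in ("core", "oav") and v.role in ("predictor", "auxiliary")
)

#: Raw predictor variables entering the analysis (before dummy expansion).
PREDICTORS = tuple(
    v.name
    for v in _SUBJECT_VARS + _SESSION_VARS
    if v.role in ("predictor", "design") and v.name not in ("time_min",)
)

#: Fixed-effect terms of the full model: THC expanded into two cumulative
#: ("sequential difference") dummies, education coded numerically.
MODEL_TERMS = (
    "dose",
    "log_time",
    "pet",
    "hallucinogen_naive",
    "age",
    "female",
    "bmi",
    "education",
    "daily_smoker",
    "alcohol",
    "thc_rarely",
    "thc_sometimes",
    "zkpq_imp_ss",
    "zkpq_n_anx",
    "zkpq_agg_host",
    "zkpq_act",
    "zkpq_sociability",
    "tas_absorption",
    "scl_gsi",
) + _EWL_SCALES

#: Binary model terms (left on their 0/1 scale by the 2-SD rescaling).
BINARY_TERMS = (
    "pet",
    "hallucinogen_naive",
    "female",
    "daily_smoker",
    "alcohol",
    "thc_rarely",
    "thc_sometimes",
)

#: Auxiliary-variable links: the auxiliary scale (key) is always offered to
#: the imputation model of its partner (value), whatever the correlation
#: screen says.
AUX_LINKS = {
    "fpi_extraversion": "zkpq_sociability",
    "fpi_emotional_lability": "zkpq_n_anx",
    "fpi_aggressiveness": "zkpq_agg_host",
    "pasi": "tas_absorption",
}


def instrument_columns(instrument: str) -> tuple[str, ...]:
    """All columns belonging to one instrument (questionnaire or item block)."""
    return tuple(v.name for v in SCHEMA.values() if v.instrument == instrument)
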