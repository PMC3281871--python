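"""Synthetic pooled-cohort generator.

Emulates a retrospective pool of experimental hallucinogen studies: repeated
drug sessions nested in subjects, subjects nested in studies, dose and
assessment time set by design, outcomes produced by a random-intercept
mixed model on a transformed scale with known (configurable) effects, and
block missingness driven purely by which questionnaires each study
administered (missing at random given study id).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import schema
from .config import CohortConfig, allocate_subjects, allocate_sessions
from .datasets import PooledDataset

__all__ = ["generate_cohort", "impose_missingness", "standardize_generating"]

logger = logging.getLogger(__name__)

_SCORE_VARS = (
    "age",
    "bmi",
    "zkpq_imp_ss",
    "zkpq_n_anx",
    "zkpq_agg_host",
    "zkpq_act",
    "zkpq_sociability",
    "tas_absorption",
    "scl_gsi",
    "fpi_extraversion",
    "fpi_emotional_lability",
    "fpi_aggressiveness",
    "pasi",
)


def _correlation_matrix(names: tuple[str, ...], pairs: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    R = np.eye(k)
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - config error path
        raise ValueError("configured correlations do not form a positive-definite matrix") from exc
    return R


def standardize_generating(name: str, values: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Predictor on the generating 2-SD standardized scale.

    Continuous variables are centred at their generating mean and divided by
    twice their generating SD; binary terms stay on 0/1 so that every
    generating coefficient is a per-two-SD (or per-category) effect on the
    transformed outcome.
    """
    if name in schema.BINARY_TERMS:
        return values.astype(float)
    marg = config.score_marginals()
    if name == "dose":
        mu, sd = config.dose_moments()
    elif name == "log_time":
        mu, sd = config.time_moments()
    elif name in marg:
        mu, sd = marg[name]
    elif name.startswith("ewl_"):
        mu, sd = 0.0, 1.0
    elif name == "education":
        p = np.asarray(config.education_probs())
        levels = np.arange(len(p), dtype=float)
        mu = float(p @ levels)
        sd = float(np.sqrt(p @ (levels - mu) ** 2))
    else:
        raise ValueError(f"no generating moments for predictor {name!r}")
    return (values - mu) / (2.0 * sd)


def _inverse_named(eta: np.ndarray, transform: str, outcome: str) -> np.ndarray:
    """Map a transformed-scale linear predictor back to the raw scale.

    Values outside the inverse-transform domain are clipped to the raw-scale
    floor (visual-analogue scales are bounded below at 0) and the event is
    logged; for the -1/sqrt transform the linear predictor is capped just
    below zero, which bounds the raw score instead of letting it diverge.
    """
    if transform == "log":
        return np.exp(eta)
    if transform == "sqrt":
        bad = eta < 0
        if bad.any():
            logger.info("outcome %s: clipped %d negative sqrt-scale values to 0", outcome, int(bad.sum()))
        return np.where(bad, 0.0, eta) ** 2
    if transform == "neg_inv_sqrt":
        cap = -0.05
        bad = eta > cap
        if bad.any():
            logger.info("outcome %s: capped %d -1/sqrt-scale values at %.2f", outcome, int(bad.sum()), cap)
        return np.minimum(eta, cap) ** -2
    if transform == "identity":
        bad = eta < 0
        if bad.any():
            logger.info("outcome %s: clipped %d negative values to 0", outcome, int(bad.sum()))
        return np.where(bad, 0.0, eta)
    raise ValueError(f"unknown transform {transform!r}")


def generate_cohort(config: CohortConfig) -> PooledDataset:
    """Generate a complete cohort (no missingness) from the configuration.

    Outcomes follow, on the transformed scale, the linear predictor
    ``intercept + X beta + b_subject + e`` with ``b ~ N(0, tau^2)`` and
    ``e ~ N(0, sigma^2)``, mapped back through the inverse of the configured
    outcome transform.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    study_of_subject = allocate_subjects(config)
    sess_counts = allocate_sessions(config)
    n_subj, n_sess = config.n_subjects, int(sess_counts.sum())

    # --- study-level design: which studies involve PET imaging ----------
    sessions_per_study = np.bincount(study_of_subject, weights=sess_counts, minlength=config.n_studies)
    share = sessions_per_study / n_sess
    order = rng.permutation(config.n_studies)
    pet_studies: set[int] = set()
    total = 0.0
    for s in order:
        if abs(total + share[s] - config.pet_study_fraction) < abs(total - config.pet_study_fraction):
            pet_studies.add(int(s))
            total += share[s]
    if not pet_studies:
        pet_studies = {int(order[0])}

    # --- subject table ---------------------------------------------------
    marg = config.score_marginals()
    pairs = dict(config.aux_correlations)
    pairs.update({p: r for p, r in config.predictor_correlations.items() if p[0] in _SCORE_VARS and p[1] in _SCORE_VARS})
    R = _correlation_matrix(_SCORE_VARS, pairs)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n_subj, len(_SCORE_VARS))) @ L.T
    scores = {name: marg[name][0] + marg[name][1] * z[:, i] for i, name in enumerate(_SCORE_VARS)}

    binm = config.binary_marginals()
    subjects = pd.DataFrame(
        {
            "subject_id": np.arange(n_subj),
            "study_id": study_of_subject,
            "age": scores["age"],
            "female": (rng.random(n_subj) < binm["female"]).astype(float),
            "education": rng.choice(3, size=n_subj, p=config.education_probs()).astype(float),
            "bmi": scores["bmi"],
            "daily_smoker": (rng.random(n_subj) < binm["daily_smoker"]).astype(float),
            "alcohol": (rng.random(n_subj) < binm["alcohol"]).astype(float),
            "thc": rng.choice(3, size=n_subj, p=config.thc_probs()).astype(float),
        }
    )
    for name in _SCORE_VARS:
        if name not in ("age", "bmi"):
            subjects[name] = scores[name]
    subjects = subjects[list(schema.SUBJECT_COLUMNS)]

    # --- session table ---------------------------------------------------
    subj_idx = np.repeat(np.arange(n_subj), sess_counts)
    occasion = np.concatenate([np.arange(1, c + 1) for c in sess_counts])
    study = study_of_subject[subj_idx]
    pet = np.isin(study, list(pet_studies)).astype(float)

    dose_levels = np.asarray(config.dose_levels, dtype=float)
    dose_idx = rng.choice(len(dose_levels), size=n_sess, p=config.dose_probs)
    # PET sessions used only the two mid-range doses, so dose varies little
    # within the PET stratum (mirrors the pooled designs).
    if len(dose_levels) >= 4:
        mid = np.array([2, 3])
        pet_rows = pet == 1
        dose_idx[pet_rows] = mid[rng.integers(0, 2, size=int(pet_rows.sum()))]
    dose = dose_levels[dose_idx]

    time_min = np.asarray(config.time_levels_min, dtype=float)[
        rng.choice(len(config.time_levels_min), size=n_sess, p=config.time_probs)
    ]

    naive0 = (rng.random(n_subj) < binm["hallucinogen_naive"]).astype(float)
    naive = np.where(occasion == 1, naive0[subj_idx], 0.0)

    ewl_pairs = {p: r for p, r in config.predictor_correlations.items() if p[0].startswith("ewl_")}
    Rewl = _correlation_matrix(schema.EWL_SCALES, ewl_pairs)
    ewl = rng.standard_normal((n_sess, len(schema.EWL_SCALES))) @ np.linalg.cholesky(Rewl).T

    sessions = pd.DataFrame(
        {
            "session_id": np.arange(n_sess),
            "subject_id": subj_idx,
            "study_id": study,
            "occasion": occasion,
            "dose": dose,
            "pet": pet,
            "time_min": time_min,
            "log_time": np.log(time_min),
            "hallucinogen_naive": naive,
        }
    )
    for i, name in enumerate(schema.EWL_SCALES):
        sessions[name] = ewl[:, i]

    # --- outcomes --------------------------------------------------------
    term_values: dict[str, np.ndarray] = {}
    merged = sessions.merge(subjects.drop(columns="study_id"), on="subject_id", how="left")
    thc = merged["thc"].to_numpy(float)
    merged["thc_rarely"] = (thc >= 1).astype(float)
    merged["thc_sometimes"] = (thc >= 2).astype(float)
    for name in config.true_beta:
        term_values[name] = standardize_generating(name, merged[name].to_numpy(float), config)

    tau, sigma = config.random_intercept_sd, config.residual_sd
    for outcome in schema.OUTCOMES:
        eta = np.full(n_sess, config.intercept_for(outcome))
        for name, beta in config.true_beta.items():
            eta = eta + beta * term_values[name]
        b = rng.normal(0.0, tau, size=n_subj)
        eta = eta + b[subj_idx] + rng.normal(0.0, sigma, size=n_sess)
        sessions[outcome] = _inverse_named(eta, config.outcome_transforms[outcome], outcome)

    sessions = sessions[list(schema.SESSION_COLUMNS)]
    data = PooledDataset(subjects, sessions)
    data.validate()
    return data


def _derive_blocks(config: CohortConfig, data: PooledDataset, rng: np.random.Generator) -> dict[str, list[int]]:
    """Choose, per instrument, the studies that did *not* administer it so
    the implied missing fraction approximates the configured target."""
    subj_share = data.subjects["study_id"].value_counts(normalize=True).reindex(range(config.n_studies), fill_value=0.0)
    sess_share = data.sessions["study_id"].value_counts(normalize=True).reindex(range(config.n_studies), fill_value=0.0)
    blocks: dict[str, list[int]] = {}
    for instrument, target in config.instrument_missing_rates.items():
        share = sess_share if instrument in ("ewl", "naive") else subj_share
        order = rng.permutation(config.n_studies)
        chosen: list[int] = []
        total = 0.0
        for s in order:
            w = float(share[s])
            if abs(total + w - target) < abs(total - target):
                chosen.append(int(s))
                total += w
        blocks[instrument] = sorted(chosen)
    return blocks


def impose_missingness(data: PooledDataset, config: CohortConfig) -> PooledDataset:
    """Blank out instruments not administered by each study (MAR given study
    id), plus an optional extra cell-wise MCAR rate; masks are recorded.

    The input dataset is not modified.
    """
    rng = np.random.default_rng([config.seed, 104729])
    known = {v.instrument for v in schema.SCHEMA.values()}
    if config.questionnaire_blocks is not None:
        for instrument in config.questionnaire_blocks:
            if instrument not in known:
                raise ValueError(f"questionnaire block references unknown instrument {instrument!r}")
        blocks = {k: list(v) for k, v in config.questionnaire_blocks.items()}
    else:
        blocks = _derive_blocks(config, data, rng)

    out = data.copy()
    subj_study = out.subjects["study_id"].to_numpy()
    sess_study = out.sessions["study_id"].to_numpy()
    for instrument, studies in blocks.items():
        cols = [c for c in schema.instrument_columns(instrument)]
        subj_cols = [c for c in cols if c in schema.IMPUTABLE_SUBJECT]
        sess_cols = [c for c in cols if c in schema.IMPUTABLE_SESSION]
        if subj_cols:
            out.subjects.loc[np.isin(subj_study, studies), subj_cols] = np.nan
        if sess_cols:
            out.sessions.loc[np.isin(sess_study, studies), sess_cols] = np.nan

    if config.extra_mcar_rate > 0:
        cols = config.mcar_columns or (schema.IMPUTABLE_SUBJECT + schema.IMPUTABLE_SESSION)
        for c in cols:
            if c in schema.IMPUTABLE_SUBJECT:
                hit = rng.random(len(out.subjects)) < config.extra_mcar_rate
                out.subjects.loc[hit, c] = np.nan
            elif c in schema.IMPUTABLE_SESSION:
                hit = rng.random(len(out.sessions)) < config.extra_mcar_rate
                out.sessions.loc[hit, c] = np.nan
            else:
                raise ValueError(f"mcar_columns references unknown imputable column {c!r}")

    out.subject_mask = out.subjects[list(schema.IMPUTABLE_SUBJECT)].isna()
    out.session_mask = out.sessions[list(schema.IMPUTABLE_SESSION)].isna()
    return out
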