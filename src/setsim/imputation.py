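"""Multiple imputation by fully conditional specification (chained equations).

Each incomplete variable gets its own conditional model — predictive mean
matching for continuous scales, a proportional-odds model for ordered
categories, logistic regression for binary flags — fitted on the currently
completed data and applied with an approximate Bayesian parameter draw, so
the imputations propagate parameter uncertainty ("proper" imputation).
Predictor sets are screened by pairwise correlation (default |r| >= 0.15),
with designated auxiliary scales always eligible for their partner.
Subject-level variables are imputed on the one-row-per-subject table and
broadcast to sessions, so a subject can never receive two different imputed
trait scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import schema
from .datasets import PooledDataset

__all__ = [
    "ImputationPlan",
    "ImputedStack",
    "build_predictor_sets",
    "fcs_impute",
    "diagnose_chains",
    "vif_screen",
    "ChainDiagnostics",
]

logger = logging.getLogger(__name__)

_KIND_TO_METHOD = {"continuous": "pmm", "binary": "logistic", "ordinal": "proportional_odds"}

#: Subject-level summaries of session variables offered as predictors when
#: imputing subject-level scales (prefix ``agg_``).
_AGG_SOURCES = ("dose", "log_time", "pet") + schema.EWL_SCALES + schema.OUTCOMES


@dataclass
class ImputationPlan:
    """Per-variable imputation methods and screened predictor sets."""

    methods: Mapping[str, str]
    predictors: Mapping[str, tuple[str, ...]]
    levels: Mapping[str, str]                 # var -> "subject" | "session"
    m: int = 20
    n_iter: int = 15
    pmm_donors: int = 5
    seed: int = 0
    threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        for var, method in self.methods.items():
            kind = schema.SCHEMA[var].kind
            if _KIND_TO_METHOD[kind] != method:
                raise ValueError(f"method {method!r} does not match kind {kind!r} of {var!r}")
            if not self.predictors.get(var):
                raise ValueError(f"empty predictor set for {var!r}")

    def set_sizes(self) -> pd.Series:
        return pd.Series({v: len(p) for v, p in self.predictors.items()}, name="n_predictors")


@dataclass
class ImputedStack:
    """m completed copies of a pooled dataset plus per-chain traces."""

    datasets: list[PooledDataset]
    traces: Mapping[str, np.ndarray]          # var -> (m, n_iter, 2): mean, sd of imputed cells
    plan: ImputationPlan
    fallback_events: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _subject_level_frame(subjects: pd.DataFrame, sessions: pd.DataFrame) -> pd.DataFrame:
    """Subject table augmented with per-subject means of session variables."""
    agg = sessions.groupby("subject_id")[list(_AGG_SOURCES)].mean()
    agg.columns = [f"agg_{c}" for c in agg.columns]
    return subjects.set_index("subject_id").join(agg).reset_index()


def _session_level_frame(subjects: pd.DataFrame, sessions: pd.DataFrame) -> pd.DataFrame:
    return sessions.merge(subjects.drop(columns="study_id"), on="subject_id", how="left")


_SUBJECT_CANDIDATES = tuple(
    c for c in schema.SUBJECT_COLUMNS if c not in ("subject_id", "study_id")
) + tuple(f"agg_{c}" for c in _AGG_SOURCES)
_SESSION_CANDIDATES = tuple(
    c for c in schema.SESSION_COLUMNS if c not in ("session_id", "subject_id", "study_id", "occasion", "time_min")
) + tuple(c for c in schema.SUBJECT_COLUMNS if c not in ("subject_id", "study_id"))


def build_predictor_sets(
    data: PooledDataset,
    threshold: float = 0.15,
    fallback_k: int = 5,
    m: int = 20,
    n_iter: int = 15,
    pmm_donors: int = 5,
    seed: int = 0,
) -> ImputationPlan:
    """Screen conditional-model predictors by pairwise correlation.

    For each incomplete variable the predictor set consists of all candidate
    variables whose absolute pairwise correlation (available cases,
    categorical variables numerically coded) reaches ``threshold``; the
    designated auxiliary scale of a variable is always eligible.  An empty
    set falls back to the ``fallback_k`` most-correlated candidates (logged).
    Session-derived subject-level summaries (``agg_`` columns) may serve as
    predictors of subject scales, which lets the outcomes inform imputation.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    subj = _subject_level_frame(data.subjects, data.sessions)
    sess = _session_level_frame(data.subjects, data.sessions)
    corr_subj = subj[list(_SUBJECT_CANDIDATES)].corr(min_periods=10)
    corr_sess = sess[list(_SESSION_CANDIDATES)].corr(min_periods=10)

    rates = data.missing_rates()
    methods: dict[str, str] = {}
    predictors: dict[str, tuple[str, ...]] = {}
    levels: dict[str, str] = {}
    aux_partners = {target: aux for aux, target in schema.AUX_LINKS.items()}
    for var in rates.index[rates > 0]:
        level = schema.SCHEMA[var].level
        corr = corr_subj if level == "subject" else corr_sess
        r = corr[var].drop(index=var).abs().dropna()
        chosen = list(r.index[r >= threshold])
        aux = aux_partners.get(var)
        if aux and aux not in chosen and aux in corr.columns:
            chosen.append(aux)
        if not chosen:
            chosen = list(r.sort_values(ascending=False).index[:fallback_k])
            logger.warning("predictor screen empty for %s; falling back to top %d", var, len(chosen))
        methods[var] = _KIND_TO_METHOD[schema.SCHEMA[var].kind]
        predictors[var] = tuple(chosen)
        levels[var] = level
    return ImputationPlan(
        methods=methods,
        predictors=predictors,
        levels=levels,
        m=m,
        n_iter=n_iter,
        pmm_donors=pmm_donors,
        seed=seed,
        threshold=threshold,
    )


# ----------------------------------------------------------------------
# Conditional draws
# ----------------------------------------------------------------------


def _bayes_lm_draw(Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator):
    """OLS fit plus a draw from the approximate parameter posterior."""
    n, k = Xo.shape
    A = Xo.T @ Xo + 1e-8 * np.eye(k)
    Ainv = np.linalg.inv(A)
    beta_hat = Ainv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - k, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(df)
    cov = sigma2_star * Ainv
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_hat, beta_star


def _pmm_impute(Xo, yo, Xm, donors, rng):
    """Predictive mean matching (type-1): observed targets of the ``donors``
    cases whose predicted means are closest to each missing case's predicted
    mean under a parameter draw."""
    beta_hat, beta_star = _bayes_lm_draw(Xo, yo, rng)
    pred_o = Xo @ beta_hat
    pred_m = Xm @ beta_star
    d = np.abs(pred_m[:, None] - pred_o[None, :])
    k = min(donors, len(yo))
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=len(Xm))
    return yo[nearest[np.arange(len(Xm)), pick]]


def _ridge_logit(Xo, yo, ridge):
    """Penalized IRLS logistic fit; returns (beta, covariance)."""
    k = Xo.shape[1]
    beta = np.zeros(k)
    for _ in range(50):
        eta = np.clip(Xo @ beta, -30, 30)
        p = expit(eta)
        w = np.maximum(p * (1 - p), 1e-6)
        H = (Xo * w[:, None]).T @ Xo + ridge * np.eye(k)
        g = Xo.T @ (yo - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta, np.linalg.inv(H)


def _logistic_impute(Xo, yo, Xm, rng, events: list[str], tag: str):
    import statsmodels.api as sm

    beta = cov = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yo, Xo).fit(disp=0, maxiter=100)
            if res.mle_retvals.get("converged", False):
                beta = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
        except Exception:
            pass
    if beta is None or not np.all(np.isfinite(cov)):
        beta, cov = _ridge_logit(Xo, yo, ridge=1.0)
        events.append(f"logistic ridge fallback: {tag}")
        logger.info("logistic separation/singularity; ridge-stabilized fallback for %s", tag)
    beta_star = rng.multivariate_normal(beta, 0.5 * (cov + cov.T), method="eigh")
    p = expit(np.clip(Xm @ beta_star, -30, 30))
    return (rng.random(len(Xm)) < p).astype(float)


def _polr_impute(Xo, yo, Xm, rng, events: list[str], tag: str):
    """Proportional-odds imputation; empirical-frequency fallback on failure."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    # thresholds act as intercepts; the constant column must not be in exog
    Xo, Xm = Xo[:, 1:], Xm[:, 1:]
    cats = np.unique(yo)
    if len(cats) < 2:
        return np.full(len(Xm), cats[0] if len(cats) else 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            endog = pd.Categorical(yo, categories=cats, ordered=True)
            model = OrderedModel(endog, Xo, distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            if not np.all(np.isfinite(cov)):
                raise ValueError("non-finite covariance")
            params_star = rng.multivariate_normal(params, 0.5 * (cov + cov.T), method="eigh")
            probs = np.asarray(model.predict(params_star, exog=Xm))
        probs = np.clip(probs, 1e-9, None)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(len(Xm))
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return cats[np.clip(idx, 0, len(cats) - 1)].astype(float)
    except Exception as exc:
        events.append(f"proportional-odds fallback ({exc.__class__.__name__}): {tag}")
        logger.info("proportional-odds fit failed (%s); empirical draw for %s", exc, tag)
        freq = np.bincount(yo.astype(int), minlength=int(cats.max()) + 1).astype(float)
        freq /= freq.sum()
        return rng.choice(len(freq), size=len(Xm), p=freq).astype(float)


# ----------------------------------------------------------------------
# The chained-equations engine
# ----------------------------------------------------------------------


def _design(frame: pd.DataFrame, cols: Sequence[str], rows: np.ndarray) -> np.ndarray:
    X = frame.loc[rows, list(cols)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def fcs_impute(data: PooledDataset, plan: ImputationPlan) -> ImputedStack:
    """Run ``plan.m`` independent chained-equation chains.

    Visits incomplete variables (ascending missing rate) for
    ``plan.n_iter`` sweeps per chain.  Observed cells are never altered;
    subject-level variables are imputed once per subject and broadcast.
    A dataset with no missing cells yields ``m`` identical copies.
    """
    if not data.has_missing:
        return ImputedStack([data.copy() for _ in range(plan.m)], {}, plan)

    rates = data.missing_rates()
    order = [v for v in rates.sort_values().index if v in plan.methods]
    subj_masks = {v: data.subject_mask[v].to_numpy() for v in order if plan.levels[v] == "subject"}
    sess_masks = {v: data.session_mask[v].to_numpy() for v in order if plan.levels[v] == "session"}
    needs_agg = any(any(p.startswith("agg_") for p in plan.predictors[v]) for v in subj_masks)

    traces = {v: np.full((plan.m, plan.n_iter, 2), np.nan) for v in order}
    events: list[str] = []
    datasets: list[PooledDataset] = []
    for chain in range(plan.m):
        rng = np.random.default_rng([plan.seed, 7919, chain])
        subjects = data.subjects.copy()
        sessions = data.sessions.copy()
        # initialize: random draws from the observed margin
        for var in order:
            table, mask = (subjects, subj_masks[var]) if var in subj_masks else (sessions, sess_masks[var])
            observed = table.loc[~mask, var].to_numpy(dtype=float)
            table.loc[mask, var] = rng.choice(observed, size=int(mask.sum()), replace=True)

        for it in range(plan.n_iter):
            subj_frame = _subject_level_frame(subjects, sessions) if needs_agg else subjects
            sess_frame = None
            for var in order:
                at_subject = var in subj_masks
                mask = subj_masks[var] if at_subject else sess_masks[var]
                if at_subject:
                    frame = subj_frame
                else:
                    if sess_frame is None:
                        sess_frame = _session_level_frame(subjects, sessions)
                    frame = sess_frame
                obs = ~mask
                Xo = _design(frame, plan.predictors[var], obs)
                Xm = _design(frame, plan.predictors[var], mask)
                yo = frame.loc[obs, var].to_numpy(dtype=float)
                tag = f"{var}@iter{it}"
                method = plan.methods[var]
                if method == "pmm":
                    imputed = _pmm_impute(Xo, yo, Xm, plan.pmm_donors, rng)
                elif method == "logistic":
                    imputed = _logistic_impute(Xo, yo, Xm, rng, events, tag)
                else:
                    imputed = _polr_impute(Xo, yo, Xm, rng, events, tag)
                target = subjects if at_subject else sessions
                target.loc[mask, var] = imputed
                frame.loc[mask, var] = imputed
                if not at_subject:
                    sess_frame = frame
                traces[var][chain, it] = (float(np.mean(imputed)), float(np.std(imputed)))
        completed = PooledDataset(
            subjects,
            sessions,
            pd.DataFrame(False, index=subjects.index, columns=list(schema.IMPUTABLE_SUBJECT)),
            pd.DataFrame(False, index=sessions.index, columns=list(schema.IMPUTABLE_SESSION)),
        )
        datasets.append(completed)
    return ImputedStack(datasets, traces, plan, events)


# ----------------------------------------------------------------------
# Diagnostics
# ----------------------------------------------------------------------


@dataclass
class ChainDiagnostics:
    table: pd.DataFrame

    @property
    def flagged(self) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table.index[self.table["flag"]])

    @property
    def empty(self) -> bool:
        return self.table.empty


def diagnose_chains(stack: ImputedStack, ratio_bound: float = 1.2) -> ChainDiagnostics:
    """Between-/within-chain variance ratio on imputed-value chain means.

    Uses the second half of each chain; the ratio ``sqrt((W + B) / W)`` is
    near 1 for well-mixed chains and is flagged above ``ratio_bound``.
    Purely descriptive — no errors are raised.
    """
    rows = {}
    for var, tr in stack.traces.items():
        means = tr[:, tr.shape[1] // 2 :, 0]  # (m, later iterations)
        W = float(np.mean(np.var(means, axis=1, ddof=1))) if means.shape[1] > 1 else np.nan
        B = float(np.var(np.mean(means, axis=1), ddof=1))
        ratio = float(np.sqrt((W + B) / W)) if W and np.isfinite(W) and W > 0 else np.inf
        drift = float(np.mean(tr[:, -1, 0] - tr[:, 0, 0]))
        rows[var] = {"within": W, "between": B, "ratio": ratio, "mean_drift": drift, "flag": ratio > ratio_bound}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ChainDiagnostics(table)


def vif_screen(
    stack: "ImputedStack | Sequence[pd.DataFrame]", predictors: Sequence[str], flag_at: float = 3.0
) -> pd.DataFrame:
    """Max variance inflation factor per predictor across imputed datasets.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing predictor j on the others
    (with intercept) within each completed dataset.  Accepts an
    :class:`ImputedStack` or a sequence of completed model frames.  Perfect
    collinearity is reported as an infinite VIF together with the
    most-correlated partner.
    """
    from .datasets import build_model_frame

    frames = (
        [build_model_frame(ds) for ds in stack.datasets]
        if isinstance(stack, ImputedStack)
        else list(stack)
    )
    max_vif = pd.Series(0.0, index=list(predictors))
    partner = pd.Series("", index=list(predictors))
    for frame in frames:
        X = frame[list(predictors)].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        for j, name in enumerate(predictors):
            others = np.delete(Xc, j, axis=1)
            yj = Xc[:, j]
            denom = float(yj @ yj)
            if denom == 0.0:
                continue
            coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
            r2 = 1.0 - float(np.sum((yj - others @ coef) ** 2)) / denom
            vif = np.inf if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
            if vif > max_vif[name]:
                max_vif[name] = vif
                if not np.isfinite(vif):
                    corr = np.corrcoef(Xc, rowvar=False)
                    k = int(np.nanargmax(np.abs(np.delete(corr[j], j))))
                    partner[name] = [p for i, p in enumerate(predictors) if i != j][k]
    out = pd.DataFrame({"max_vif": max_vif, "flag": max_vif > flag_at, "collinear_with": partner})
    return out
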