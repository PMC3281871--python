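"""Two-step bootstrap backward-elimination variable selection.

Step 1: within each completed (imputed) dataset, B bootstrap samples are
drawn from individual sessions (rows) with replacement at the original
sample size; backward elimination with a Wald stopping rule of p = 0.157 —
the significance level at which dropping a 1-df predictor coincides with
AIC-based selection — is run on every sample, and predictors present in at
least a ``cutoff`` fraction of the m x B final models are retained.
Step 2 repeats the procedure starting from the retained set and records
exact final-model identities; the modal model is the "most stable" model.
First-order interactions with the dose variable are then screened within
that model via pooled posterior p-values, reported but never auto-added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import inference
from .lmm import ModelFormula, SufficientStats, SingularDesignError, design_matrices, sample_posterior

__all__ = [
    "SelectionResult",
    "backward_eliminate",
    "aic_alpha_equivalence",
    "bootstrap_select",
    "two_step_select",
    "screen_interactions",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of bootstrap variable selection for one response."""

    outcome: str
    step1_frequencies: pd.Series | None = None
    retained: tuple[str, ...] | None = None
    cutoff: float = 0.5
    step2_model_frequencies: Mapping[tuple[str, ...], float] | None = None
    most_stable_model: ModelFormula | None = None
    interaction_table: pd.DataFrame | None = None
    n_redrawn: int = 0

    def step2_table(self) -> pd.DataFrame:
        if not self.step2_model_frequencies:
            return pd.DataFrame(columns=["model", "frequency"])
        rows = [
            {"model": " + ".join(mod), "frequency": f}
            for mod, f in sorted(self.step2_model_frequencies.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def aic_alpha_equivalence(penalty: float = 2.0) -> float:
    """Wald-dropping significance level equivalent to AIC selection.

    Removing a 1-df predictor lowers the AIC exactly when its likelihood-
    ratio chi-square falls short of the penalty per parameter, so the
    equivalent alpha is the upper-tail chi-square(1) probability at
    ``penalty`` (0.157 for the conventional penalty of 2).
    """
    return float(stats.chi2.sf(penalty, df=1))


def _eliminate_on_stats(
    ss: SufficientStats,
    candidate_idx: list[int],
    locked_idx: list[int],
    alpha: float,
) -> tuple[list[int], list[int]]:
    """Backward elimination on precomputed sufficient statistics.

    Returns (surviving candidate column indices, drop sequence).  Ties on
    the largest p-value are broken by dropping the term that comes later in
    the declared predictor order (deterministic).
    """
    active = sorted(candidate_idx + locked_idx)
    candidates = set(candidate_idx)
    dropped: list[int] = []
    while True:
        sub = ss.subset(active)
        fit = sub.fit(reml=False)
        pvals = fit.pvalues
        worst_p = -1.0
        worst_col = None
        for pos, col in enumerate(active):
            if col in candidates and pvals[pos] >= worst_p:  # >= keeps the later term on ties
                worst_p, worst_col = pvals[pos], col
        if worst_col is None or worst_p <= alpha:
            return [c for c in active if c in candidates], dropped
        active.remove(worst_col)
        candidates.remove(worst_col)
        dropped.append(worst_col)


def backward_eliminate(
    formula: ModelFormula,
    data: pd.DataFrame,
    alpha: float = 0.157,
    return_sequence: bool = False,
):
    """Drop the worst-p predictor (Wald, z reference) until all p <= alpha.

    The intercept and the subject random intercept are never candidates,
    nor are the formula's ``locked`` terms.  Deterministic given the data.
    """
    X, y, groups, names = design_matrices(data, formula)
    ss = SufficientStats(X, y, groups, names)
    locked = [0] + [names.index(t) for t in formula.locked]
    candidates = [i for i in range(len(names)) if i not in locked]
    surviving, dropped = _eliminate_on_stats(ss, candidates, locked, alpha)
    keep = sorted(set(surviving) | set(locked) - {0})
    reduced = ModelFormula(
        formula.outcome,
        tuple(p for p in formula.predictors if names.index(p) in keep),
        formula.group,
        formula.locked,
    )
    if return_sequence:
        return reduced, [names[i] for i in dropped]
    return reduced


def _bootstrap_stats(
    Z: np.ndarray, groups: np.ndarray, rows: np.ndarray, names, gb: np.ndarray | None = None
) -> SufficientStats:
    """Sufficient statistics of a row-resampled dataset (fast path)."""
    n, p1 = Z.shape
    Zb = Z[rows]
    if gb is None:
        gb = groups[rows]
    n_groups = int(gb.max()) + 1
    S = np.empty((n_groups, p1))
    for j in range(p1):
        S[:, j] = np.bincount(gb, weights=Zb[:, j], minlength=n_groups)
    counts = np.bincount(gb, minlength=n_groups)
    present = counts > 0
    counts = counts[present]
    S = S[present]
    sizes, inverse = np.unique(counts, return_inverse=True)
    H = np.empty((len(sizes), p1, p1))
    for k in range(len(sizes)):
        Sk = S[inverse == k]
        H[k] = Sk.T @ Sk
    ss = object.__new__(SufficientStats)
    ss.names = names
    ss.G = Zb.T @ Zb
    ss.H = H
    ss.sizes = sizes.astype(float)
    ss.size_counts = np.bincount(inverse).astype(float)
    ss.n = len(rows)
    ss.n_groups = int(present.sum())
    return ss


def bootstrap_select(
    frames: Sequence[pd.DataFrame],
    full: ModelFormula,
    B: int = 200,
    cutoff: float = 0.5,
    step: int = 1,
    seed: int = 0,
    alpha: float = 0.157,
    max_redraws: int = 20,
    resample: str = "sessions",
) -> SelectionResult:
    """One step of the bootstrap selection over a stack of completed frames.

    ``frames`` are the m completed, rescaled model frames (one per imputed
    dataset).  Per (imputation, replicate) a session-level bootstrap sample
    of the original size is drawn with its own counter-derived seed; a
    sample on which the full design is singular is redrawn (counted).
    Step 1 records per-predictor membership of the final models and retains
    predictors with frequency >= ``cutoff``; step 2 records exact model
    identities and the modal ("most stable") model.

    ``resample='sessions'`` draws individual sessions (rows), the default
    and the procedure's canonical form even though observations are
    clustered; ``resample='subjects'`` draws whole subjects with
    replacement (all their sessions), which respects the clustering.
    """
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    if resample not in ("sessions", "subjects"):
        raise ValueError("resample must be 'sessions' or 'subjects'")
    membership = {p: 0 for p in full.predictors}
    model_counts: dict[tuple[str, ...], int] = {}
    names = ("Intercept", *full.predictors)
    locked = [0] + [names.index(t) for t in full.locked]
    candidate_idx = [i for i in range(len(names)) if i not in locked]
    n_redrawn = 0
    total = 0
    for d, frame in enumerate(frames):
        X, y, groups, _ = design_matrices(frame, full)
        Z = np.column_stack([X, y])
        n = len(y)
        n_groups = int(groups.max()) + 1
        rows_by_group = [np.where(groups == g)[0] for g in range(n_groups)] if resample == "subjects" else None
        for b in range(B):
            rng = np.random.default_rng([seed, d, b])
            for attempt in range(max_redraws + 1):
                if rows_by_group is None:
                    rows = rng.integers(0, n, size=n)
                    gb = None
                else:
                    # each drawn subject becomes its own cluster in the resample
                    picked = rng.integers(0, n_groups, size=n_groups)
                    chunks = [rows_by_group[g] for g in picked]
                    rows = np.concatenate(chunks)
                    gb = np.repeat(np.arange(n_groups), [len(c) for c in chunks])
                ss = _bootstrap_stats(Z, groups, rows, names, gb)
                try:
                    surviving, _ = _eliminate_on_stats(ss, candidate_idx, locked, alpha)
                    break
                except SingularDesignError:
                    n_redrawn += 1
                    if attempt == max_redraws:
                        raise
            final_terms = tuple(
                p for i, p in enumerate(full.predictors, start=1) if i in surviving or i in locked
            )
            for t in final_terms:
                membership[t] += 1
            model_counts[final_terms] = model_counts.get(final_terms, 0) + 1
            total += 1
    freqs = pd.Series({p: membership[p] / total for p in full.predictors}, name="inclusion_frequency")
    if step == 1:
        retained = tuple(p for p in full.predictors if freqs[p] >= cutoff)
        return SelectionResult(
            full.outcome, step1_frequencies=freqs, retained=retained, cutoff=cutoff, n_redrawn=n_redrawn
        )
    model_freqs = {mod: c / total for mod, c in model_counts.items()}
    modal = min(model_freqs.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    most_stable = ModelFormula(full.outcome, modal, full.group, tuple(t for t in full.locked if t in modal))
    return SelectionResult(
        full.outcome,
        step1_frequencies=freqs,
        cutoff=cutoff,
        step2_model_frequencies=model_freqs,
        most_stable_model=most_stable,
        n_redrawn=n_redrawn,
    )


def two_step_select(
    frames: Sequence[pd.DataFrame],
    full: ModelFormula,
    B: int = 200,
    cutoff: float = 0.5,
    seed: int = 0,
    alpha: float = 0.157,
) -> SelectionResult:
    """Run both selection steps; step 2 starts from the step-1 retained set."""
    step1 = bootstrap_select(frames, full, B=B, cutoff=cutoff, step=1, seed=seed, alpha=alpha)
    retained = step1.retained or ()
    if not retained:
        logger.warning("no predictor reached the %.0f%% cutoff for %s", 100 * cutoff, full.outcome)
        return step1
    reduced = ModelFormula(full.outcome, retained, full.group, tuple(t for t in full.locked if t in retained))
    step2 = bootstrap_select(frames, reduced, B=B, cutoff=cutoff, step=2, seed=seed + 1, alpha=alpha)
    return SelectionResult(
        full.outcome,
        step1_frequencies=step1.step1_frequencies,
        retained=retained,
        cutoff=cutoff,
        step2_model_frequencies=step2.step2_model_frequencies,
        most_stable_model=step2.most_stable_model,
        n_redrawn=step1.n_redrawn + step2.n_redrawn,
    )


def screen_interactions(
    frames: Sequence[pd.DataFrame],
    model: ModelFormula,
    base: str = "dose",
    alpha_report: float = 0.05,
    alpha_flag: float = 0.01,
    candidates: Sequence[str] | None = None,
    n_draws: int = 600,
    burn: int = 200,
    seed: int = 0,
    low_variability_fraction: float = 0.5,
) -> pd.DataFrame:
    """Screen first-order ``base x predictor`` interactions in the model.

    Each interaction is added (one at a time) to the model on every
    completed frame, its posterior is sampled and pooled across frames, and
    the two-tailed posterior p is reported at the ``alpha_report`` and
    ``alpha_flag`` levels.  Interactions are reported only — never added to
    the model.  If the base predictor varies little within a level of a
    binary partner (within-level SD below ``low_variability_fraction`` of
    its overall SD), the row carries a low-variability warning since the
    interaction is then poorly identified.
    """
    if base not in model.predictors:
        raise ValueError(f"base predictor {base!r} not in model")
    if candidates is None:
        candidates = [p for p in model.predictors if p != base]
    rows = []
    base_sd = float(np.std(frames[0][base].to_numpy(float), ddof=1))
    for j, term in enumerate(candidates):
        colname = f"{base}:{term}"
        draws_per_frame = []
        untestable = False
        for d, frame in enumerate(frames):
            work = frame.copy()
            work[colname] = work[base] * work[term]
            inter_formula = ModelFormula(
                model.outcome, model.predictors + (colname,), model.group, model.locked
            )
            X, _, _, _ = design_matrices(work, inter_formula)
            # interaction column (numerically) inside the main-effect span?
            resid = work[colname].to_numpy(float) - X[:, :-1] @ np.linalg.lstsq(X[:, :-1], X[:, -1], rcond=None)[0]
            denom = float(np.var(X[:, -1])) or 1.0
            if float(resid @ resid) / (len(resid) * denom) < 1e-10:
                untestable = True
                break
            draws_per_frame.append(
                sample_posterior(
                    inter_formula, work, n_draws=n_draws, burn=burn, thin=1, seed=[seed, j, d],
                    ess_floor=0.0,  # report-only screen; short chains are acceptable
                )
            )
        row: dict = {"term": colname}
        if untestable:
            row.update({"estimate": np.nan, "p": np.nan, "untestable": True, "flag": ""})
        else:
            pooled = inference.pool_posteriors(draws_per_frame)
            est = pooled.table.loc[colname]
            p = float(est["p"])
            row.update(
                {
                    "estimate": float(est["estimate"]),
                    "hpd_low": float(est["hpd_low"]),
                    "hpd_high": float(est["hpd_high"]),
                    "p": p,
                    "untestable": False,
                    "flag": "**" if p < alpha_flag else ("*" if p < alpha_report else ""),
                }
            )
        # identification warning for binary partners
        warn = False
        tvals = frames[0][term].to_numpy(float)
        if len(np.unique(tvals)) <= 2 and base_sd > 0:
            for level in np.unique(tvals):
                sub = frames[0].loc[tvals == level, base].to_numpy(float)
                if len(sub) > 1 and float(np.std(sub, ddof=1)) < low_variability_fraction * base_sd:
                    warn = True
        row["low_base_variability"] = warn
        if warn:
            logger.warning("interaction %s: little dose variability within a level of %s", colname, term)
        rows.append(row)
    return pd.DataFrame(rows).set_index("term")
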