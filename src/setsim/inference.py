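"""Pooled inference after multiple imputation.

Final estimates mix equal numbers of posterior draws across the m completed
datasets; the mixed draws approximate the posterior of the pooled
parameters, giving means, narrowest 95% highest-posterior-density intervals
and two-tailed posterior p-values directly.  Rubin's rules on the
per-imputation summaries supply the relative increase in variance (RIV) and
fraction of missing information (FMI).  Model fit is summarised by the
Wald-F-based R-squared for the fixed effects of a mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from .lmm import LmmFit, PosteriorDraws

__all__ = [
    "PooledEstimate",
    "FitDiagnostics",
    "hpd_interval",
    "pool_posteriors",
    "rubins_rules",
    "edwards_r2",
    "significance_stars",
]


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PooledEstimate:
    """Pooled fixed-effect summaries across imputations.

    ``table`` columns: estimate, hpd_low, hpd_high, p, stars, W (mean
    within-imputation variance), B (between-imputation variance), T (total
    variance), riv, fmi.
    """

    table: pd.DataFrame
    m: int
    draws_per_imputation: int

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def pool_posteriors(draws_list: Sequence[PosteriorDraws], mass: float = 0.95) -> PooledEstimate:
    """Mix equal numbers of posterior draws across imputations.

    The pooled p-value is ``2 * min(Pr(beta > 0), Pr(beta < 0))`` on the
    mixed draws, floored at 2 / (total draws); the interval is the
    narrowest one holding ``mass``.  Per-coefficient RIV/FMI come from
    Rubin's rules applied to the per-imputation posterior means and
    variances.
    """
    if not draws_list:
        raise ValueError("no posterior draws to pool")
    names = draws_list[0].names
    for d in draws_list[1:]:
        if d.names != names:
            a, b = set(names), set(d.names)
            raise ValueError(f"coefficient sets differ between imputations: {sorted(a ^ b)}")
    m = len(draws_list)
    n_keep = min(d.n_draws for d in draws_list)
    stacks = [d.draws.iloc[:n_keep].to_numpy() for d in draws_list]
    pooled = np.vstack(stacks)
    total = pooled.shape[0]

    rows = {}
    for j, name in enumerate(names):
        col = pooled[:, j]
        lo, hi = hpd_interval(col, mass)
        p_pos = float(np.mean(col > 0))
        p = 2.0 * min(p_pos, 1.0 - p_pos)
        p = min(1.0, max(p, 2.0 / total))
        est = {"estimate": float(col.mean()), "hpd_low": lo, "hpd_high": hi, "p": p, "stars": significance_stars(p)}
        if m >= 2:
            means = np.array([s[:, j].mean() for s in stacks])
            variances = np.array([s[:, j].var(ddof=1) for s in stacks])
            W, B, T, riv, fmi = rubins_rules(means, variances, m)
            est.update({"W": W, "B": B, "T": T, "riv": riv, "fmi": fmi})
        else:
            est.update({"W": np.nan, "B": np.nan, "T": np.nan, "riv": np.nan, "fmi": np.nan})
        rows[name] = est
    return PooledEstimate(pd.DataFrame.from_dict(rows, orient="index"), m=m, draws_per_imputation=n_keep)


def rubins_rules(
    estimates: Sequence[float], variances: Sequence[float], m: int | None = None
) -> tuple[float, float, float, float, float]:
    """Combine per-imputation point estimates and variances.

    Returns ``(W, B, T, RIV, FMI)`` with ``W`` the mean within-imputation
    variance, ``B`` the between-imputation variance of the estimates,
    ``T = W + (1 + 1/m) B``, ``RIV = (1 + 1/m) B / W`` and
    ``FMI = (RIV + 2/(nu + 3)) / (1 + RIV)`` where ``nu`` is the standard
    large-sample degrees-of-freedom ``(m - 1)(1 + 1/RIV)^2``.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if m is None:
        m = len(estimates)
    if m < 2:
        raise ValueError("Rubin's rules require m >= 2")
    W = float(variances.mean())
    B = float(estimates.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if W == 0.0:
        warnings.warn("mean within-imputation variance is zero; RIV undefined (reported as inf)")
        riv = np.inf
        fmi = 1.0
        return W, B, T, riv, fmi
    riv = (1.0 + 1.0 / m) * B / W
    if riv == 0.0:
        return W, B, T, 0.0, 0.0
    nu = (m - 1.0) * (1.0 + 1.0 / riv) ** 2
    fmi = (riv + 2.0 / (nu + 3.0)) / (1.0 + riv)
    return W, B, T, riv, fmi


@dataclass
class FitDiagnostics:
    """Fixed-effect fit summary of one mixed model."""

    r2: float
    f_stat: float
    q: int          # numerator df: non-intercept fixed effects
    nu2: float      # denominator df (residual/containment approximation)

    def as_dict(self) -> dict:
        return {"r2": self.r2, "f": self.f_stat, "q": self.q, "nu2": self.nu2}


def edwards_r2(fit: LmmFit) -> FitDiagnostics:
    """R-squared for the fixed effects of a mixed model, from the Wald F.

    The joint Wald F for the null that all ``q`` non-intercept fixed
    effects vanish is converted to
    ``R^2 = (q/nu2 * F) / (1 + q/nu2 * F)`` with the residual-type
    denominator df ``nu2 = n - q - 1`` (a containment-style approximation;
    at the sample sizes this package targets the choice of denominator df
    is immaterial).  An intercept-only model has ``R^2 = 0`` by definition.
    """
    q = fit.q
    nu2 = float(fit.n - q - 1)
    if nu2 <= 0:
        raise ValueError(f"non-positive denominator df ({nu2}); model too large for n={fit.n}")
    if q == 0:
        return FitDiagnostics(0.0, 0.0, 0, nu2)
    beta = fit.beta[1:]
    cov = fit.cov[1:, 1:]
    F = float(beta @ np.linalg.solve(cov, beta)) / q
    ratio = q / nu2 * F
    return FitDiagnostics(ratio / (1.0 + ratio), F, q, nu2)


def pool_r2(diagnostics: Sequence[FitDiagnostics], how: str = "mean") -> float:
    """Combine per-imputation R-squared values (arithmetic mean by default;
    ``how='median'`` as the robust alternative)."""
    vals = np.array([d.r2 for d in diagnostics])
    if how == "median":
        return float(np.median(vals))
    if how != "mean":
        raise ValueError("how must be 'mean' or 'median'")
    return float(vals.mean())
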