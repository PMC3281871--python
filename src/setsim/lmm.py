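"""Random-intercept linear mixed model: fast profiled ML/REML fitting,
Wald tests, and Gibbs posterior sampling of the fixed effects.

The model is ``y = X beta + b[group] + e`` with ``b ~ N(0, tau^2)`` per
subject and ``e ~ N(0, sigma^2)``.  Writing ``theta = tau^2/sigma^2``, the
marginal covariance within a group of size ``s`` is
``sigma^2 (I + theta J)``, whose inverse and determinant are closed-form.
All fits therefore reduce to a one-dimensional profiled optimization over
``theta`` using group-wise sufficient statistics; refits on column subsets
(backward elimination) and on bootstrap resamples reuse the same machinery,
which is what makes the bootstrap selection procedure tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from . import _core

__all__ = [
    "ModelFormula",
    "LmmFit",
    "PosteriorDraws",
    "SufficientStats",
    "fit_lmm",
    "wald_p",
    "sample_posterior",
    "ConvergenceError",
    "SingularDesignError",
]

_LOG2PI = math.log(2.0 * math.pi)
_THETA_MAX = 1e4
_RSS_FLOOR = 1e-12


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the fixed-effect design is (numerically) singular."""


class ConvergenceError(RuntimeError):
    """Raised when the posterior sampler fails its effective-size floor."""


@dataclass(frozen=True)
class ModelFormula:
    """Fixed-effect specification of a random-intercept model.

    ``locked`` predictors (e.g. a covariate forced into every model) are
    never candidates for elimination; the intercept and the subject random
    intercept are implicit and always present.
    """

    outcome: str
    predictors: tuple[str, ...]
    group: str = "subject_id"
    locked: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors in formula")
        unknown_locked = set(self.locked) - set(self.predictors)
        if unknown_locked:
            raise ValueError(f"locked terms not among predictors: {sorted(unknown_locked)}")

    def drop(self, term: str) -> "ModelFormula":
        return ModelFormula(
            self.outcome,
            tuple(p for p in self.predictors if p != term),
            self.group,
            self.locked,
        )


@dataclass
class LmmFit:
    """Estimates from one random-intercept fit (standardized units)."""

    names: tuple[str, ...]           # fixed-effect names, intercept first
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    sigma2: float
    loglik: float
    aic: float
    n: int
    n_groups: int
    method: str                      # "ML" | "REML"
    cov: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def q(self) -> int:
        """Number of non-intercept fixed effects."""
        return len(self.names) - 1

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.names), name="beta")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "z": self.zvalues, "p": self.pvalues},
            index=list(self.names),
        )


class SufficientStats:
    """Group-wise sufficient statistics for profiled random-intercept fits.

    Stores ``G = Z'Z`` with ``Z = [X, y]`` and, for each distinct group size
    ``s``, the sum of outer products of group-wise column sums.  Any fit on a
    subset of the columns of ``X`` is then a cheap matrix-slice, which
    backward elimination exploits heavily.
    """

    __slots__ = ("names", "G", "H", "sizes", "size_counts", "n", "n_groups")

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, names: Sequence[str]):
        n, p = X.shape
        Z = np.empty((n, p + 1))
        Z[:, :p] = X
        Z[:, p] = y
        n_groups = int(groups.max()) + 1 if n else 0
        S = np.empty((n_groups, p + 1))
        for j in range(p + 1):
            S[:, j] = np.bincount(groups, weights=Z[:, j], minlength=n_groups)
        counts = np.bincount(groups, minlength=n_groups)
        present = counts > 0
        counts = counts[present]
        S = S[present]
        sizes, inverse = np.unique(counts, return_inverse=True)
        H = np.empty((len(sizes), p + 1, p + 1))
        for k in range(len(sizes)):
            Sk = S[inverse == k]
            H[k] = Sk.T @ Sk
        self.names = tuple(names)
        self.G = Z.T @ Z
        self.H = H
        self.sizes = sizes.astype(float)
        self.size_counts = np.bincount(inverse).astype(float)
        self.n = n
        self.n_groups = int(present.sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, formula: ModelFormula) -> "SufficientStats":
        X, y, groups, names = design_matrices(frame, formula)
        return cls(X, y, groups, names)

    def subset(self, keep: Sequence[int]) -> "SufficientStats":
        """Restrict to a subset of X columns (y is kept automatically)."""
        idx = list(keep) + [self.G.shape[0] - 1]
        new = object.__new__(SufficientStats)
        new.names = tuple(self.names[i] for i in keep)
        new.G = self.G[np.ix_(idx, idx)]
        new.H = self.H[:, idx][:, :, idx]
        new.sizes = self.sizes
        new.size_counts = self.size_counts
        new.n = self.n
        new.n_groups = self.n_groups
        return new

    # ------------------------------------------------------------------
    def _crossprod(self, theta: float) -> np.ndarray:
        """``Z' V*^{-1} Z`` where ``V* = I + theta * block-J``."""
        if theta == 0.0:
            return self.G
        c = theta / (1.0 + self.sizes * theta)
        return self.G - np.tensordot(c, self.H, axes=1)

    def _profile(self, theta: float, reml: bool):
        A = self._crossprod(theta)
        p = A.shape[0] - 1
        try:
            cf = sla.cho_factor(A[:p, :p], lower=True, check_finite=False)
        except (sla.LinAlgError, ValueError) as exc:
            raise SingularDesignError(str(exc)) from None
        beta = sla.cho_solve(cf, A[:p, p], check_finite=False)
        rss = max(float(A[p, p] - A[:p, p] @ beta), _RSS_FLOOR)
        logdet_v = float(self.size_counts @ np.log1p(self.sizes * theta))
        if reml:
            df = self.n - p
            dev = df * (_LOG2PI + 1.0 + math.log(rss / df)) + logdet_v
            dev += 2.0 * float(np.log(np.diag(cf[0])).sum())
            sigma2 = rss / df
        else:
            dev = self.n * (_LOG2PI + 1.0 + math.log(rss / self.n)) + logdet_v
            sigma2 = rss / self.n
        return dev, beta, sigma2, cf

    def fit(self, reml: bool = False, xatol: float = 1e-6) -> LmmFit:
        if _core.HAVE_NUMBA:
            theta = float(
                _core.fit_theta(self.G, self.H, self.sizes, self.size_counts, self.n, reml)
            )
            dev, beta, sigma2, cf = self._profile(theta, reml)
        else:
            def objective(t: float) -> float:
                return self._profile(t, reml)[0]

            res = optimize.minimize_scalar(
                objective, bounds=(0.0, _THETA_MAX), method="bounded", options={"xatol": xatol}
            )
            theta = float(res.x)
            dev = float(res.fun)
            dev0 = objective(0.0)
            if dev0 <= dev:
                theta, dev = 0.0, dev0
            dev, beta, sigma2, cf = self._profile(theta, reml)
        p = len(beta)
        cov = sigma2 * sla.cho_solve(cf, np.eye(p), check_finite=False)
        se = np.sqrt(np.diag(cov))
        loglik = -0.5 * dev
        n_par = p + 2  # fixed effects + tau^2 + sigma^2
        return LmmFit(
            names=self.names,
            beta=beta,
            se=se,
            tau2=theta * sigma2,
            sigma2=sigma2,
            loglik=loglik,
            aic=dev + 2.0 * n_par,
            n=self.n,
            n_groups=self.n_groups,
            method="REML" if reml else "ML",
            cov=cov,
        )


def design_matrices(
    frame: pd.DataFrame, formula: ModelFormula
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Build ``(X, y, group_codes, names)`` from a completed model frame."""
    cols = [formula.outcome, *formula.predictors, formula.group]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise KeyError(f"columns absent from model frame: {missing}")
    sub = frame[cols]
    if sub[[formula.outcome, *formula.predictors]].isna().to_numpy().any():
        raise ValueError("model frame contains missing values; impute first")
    n = len(sub)
    X = np.empty((n, len(formula.predictors) + 1))
    X[:, 0] = 1.0
    for j, name in enumerate(formula.predictors, start=1):
        X[:, j] = sub[name].to_numpy(dtype=float)
    y = sub[formula.outcome].to_numpy(dtype=float)
    groups = pd.factorize(sub[formula.group])[0]
    return X, y, groups, ("Intercept", *formula.predictors)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    return [names[i] for i in np.where(diag <= tol)[0]]


def fit_lmm(formula: ModelFormula, data: pd.DataFrame, criterion: str = "ML") -> LmmFit:
    """Fit the random-intercept model by (restricted) maximum likelihood.

    ``criterion='ML'`` is used whenever models are compared by AIC or
    likelihood (e.g. during selection); REML is available for variance
    component reporting.  A boundary estimate ``tau^2 = 0`` is allowed.
    """
    if criterion not in ("ML", "REML"):
        raise ValueError("criterion must be 'ML' or 'REML'")
    X, y, groups, names = design_matrices(data, formula)
    ss = SufficientStats(X, y, groups, names)
    try:
        return ss.fit(reml=criterion == "REML")
    except SingularDesignError:
        bad = _collinear_columns(X, names)
        raise SingularDesignError(f"singular fixed-effect design; collinear columns: {bad or 'unknown'}") from None


def wald_p(fit: LmmFit, term: str) -> float:
    """Two-sided Wald p-value of one fixed effect (Gaussian reference).

    The Gaussian (z) reference is used rather than a t with approximated
    degrees of freedom: denominator df are ill-defined in mixed models, the
    final inference is posterior-based, and selection only needs a
    consistent ranking rule.
    """
    if term not in fit.names:
        raise KeyError(f"term {term!r} not in fit (has {fit.names})")
    i = fit.names.index(term)
    return float(2.0 * stats.norm.sf(abs(fit.beta[i] / fit.se[i])))


# ----------------------------------------------------------------------
# Posterior sampling
# ----------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Fixed-effect posterior draws from one completed dataset."""

    draws: pd.DataFrame               # n_draws x fixed effects
    tau2: np.ndarray
    sigma2: np.ndarray
    seed: int | Sequence[int]
    ess: pd.Series

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.draws.columns)

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def sample_posterior(
    formula: ModelFormula,
    data: pd.DataFrame,
    n_draws: int = 2000,
    seed: int | Sequence[int] = 0,
    burn: int = 500,
    thin: int = 2,
    prior_scale: float = 2.5,
    ess_floor: float = 20.0,
) -> PosteriorDraws:
    """Gibbs sampler for the Gaussian random-intercept model.

    Priors: flat on the fixed effects, half-Cauchy(``prior_scale``) on both
    the subject-intercept SD and the residual SD (implemented as
    inverse-gamma scale mixtures, so every conditional stays conjugate).
    Draws are recorded after ``burn`` iterations with the given thinning and
    are reproducible from ``seed``.  Raises :class:`ConvergenceError` when
    the smallest fixed-effect effective sample size falls below
    ``ess_floor``.
    """
    X, y, groups, names = design_matrices(data, formula)
    n, p = X.shape
    n_groups = int(groups.max()) + 1
    rng = np.random.default_rng(seed)

    XtX = X.T @ X
    try:
        cf = sla.cho_factor(XtX, lower=True, check_finite=False)
    except sla.LinAlgError:
        raise SingularDesignError(f"singular design; collinear columns: {_collinear_columns(X, names)}")
    Xty = X.T @ y
    Lt_inv = sla.solve_triangular(cf[0], np.eye(p), lower=True, check_finite=False).T
    SX = np.empty((n_groups, p))
    for j in range(p):
        SX[:, j] = np.bincount(groups, weights=X[:, j], minlength=n_groups)
    ng = np.bincount(groups, minlength=n_groups).astype(float)

    beta = sla.cho_solve(cf, Xty, check_finite=False)
    resid = y - X @ beta
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-8)
    tau2 = 0.1 * sigma2
    b = np.zeros(n_groups)
    xi_s = xi_t = 1.0
    A2 = prior_scale**2

    kept = np.empty((n_draws, p))
    kept_t2 = np.empty(n_draws)
    kept_s2 = np.empty(n_draws)
    total = burn + n_draws * thin
    k = 0
    for it in range(total):
        # subject intercepts
        resid0 = y - X @ beta
        rg = np.bincount(groups, weights=resid0, minlength=n_groups)
        v = 1.0 / (ng / sigma2 + 1.0 / tau2)
        b = v * rg / sigma2 + np.sqrt(v) * rng.standard_normal(n_groups)
        # fixed effects (flat prior)
        rhs = Xty - SX.T @ b
        mean = sla.cho_solve(cf, rhs, check_finite=False)
        beta = mean + math.sqrt(sigma2) * (Lt_inv @ rng.standard_normal(p))
        # variance components: half-Cauchy via inverse-gamma mixture
        e = y - X @ beta - b[groups]
        rss = float(e @ e)
        xi_s = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / sigma2)
        sigma2 = _inv_gamma(rng, 0.5 * (n + 1.0), 1.0 / xi_s + 0.5 * rss)
        xi_t = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / tau2)
        tau2 = _inv_gamma(rng, 0.5 * (n_groups + 1.0), 1.0 / xi_t + 0.5 * float(b @ b))
        if it >= burn and (it - burn) % thin == 0:
            kept[k] = beta
            kept_t2[k] = tau2
            kept_s2[k] = sigma2
            k += 1
    draws = pd.DataFrame(kept, columns=list(names))
    ess = pd.Series({nm: effective_sample_size(kept[:, j]) for j, nm in enumerate(names)})
    if float(ess.min()) < ess_floor:
        raise ConvergenceError(
            f"posterior sampler effective size below floor ({float(ess.min()):.1f} < {ess_floor}); ess={ess.to_dict()}"
        )
    return PosteriorDraws(draws=draws, tau2=kept_t2, sigma2=kept_s2, seed=seed, ess=ess)
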