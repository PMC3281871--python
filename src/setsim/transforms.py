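"""Outcome transformation and modelling-scale rescaling.

The outcome scales are bounded-below visual-analogue scores whose residuals
are typically right-skewed; a Box-Cox power is therefore profiled against
the random-intercept mixed-model likelihood (including the Jacobian of the
transformation) and snapped to the nearest interpretable named transform:
log (lambda = 0), square root (0.5), negative inverse square root (-0.5) or
identity (1).  Predictors are never transformed; for comparability of
coefficients, continuous predictors are rescaled by twice their standard
deviation (so a binary predictor, SD ~ 0.5, and a continuous one move on
the same per-two-SD scale) and transformed outcomes are z-scored within
each completed dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import schema
from .lmm import SufficientStats

__all__ = [
    "TransformSpec",
    "NAMED_LAMBDAS",
    "select_boxcox_lambda",
    "apply_transform",
    "inverse_transform",
    "rescale_for_modeling",
    "ScalingRecord",
    "TransformDomainError",
]

NAMED_LAMBDAS = {"log": 0.0, "sqrt": 0.5, "neg_inv_sqrt": -0.5, "identity": 1.0}
_LAMBDA_TO_NAME = {v: k for k, v in NAMED_LAMBDAS.items()}
_DEFAULT_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)


class TransformDomainError(ValueError):
    """Raised when values lie outside a transform's domain."""


@dataclass(frozen=True)
class TransformSpec:
    """A selected or configured outcome transform.

    ``lam`` is the Box-Cox power; when it equals a named power the transform
    is applied in its conventional named form (log y, sqrt y, -1/sqrt y, y),
    which is a monotone affine relabelling of the Box-Cox form and therefore
    likelihood-equivalent.  ``offset`` is added to the raw scores before
    transforming (used when exact zeros occur).
    """

    outcome: str
    lam: float
    named_transform: str | None = None
    provenance: str = "configured"  # "selected" | "configured"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.named_transform is not None:
            expected = NAMED_LAMBDAS.get(self.named_transform)
            if expected is None:
                raise ValueError(f"unknown named transform {self.named_transform!r}")
            if not np.isclose(expected, self.lam):
                raise ValueError(
                    f"named transform {self.named_transform!r} inconsistent with lambda {self.lam}"
                )

    @classmethod
    def from_name(cls, outcome: str, name: str, provenance: str = "configured", offset: float = 0.0) -> "TransformSpec":
        return cls(outcome, NAMED_LAMBDAS[name], name, provenance, offset)

    def apply(self, y: np.ndarray) -> np.ndarray:
        return apply_transform(np.asarray(y, dtype=float), self)

    def inverse(self, t: np.ndarray) -> np.ndarray:
        return inverse_transform(np.asarray(t, dtype=float), self)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "lambda": self.lam,
            "named_transform": self.named_transform,
            "provenance": self.provenance,
            "offset": self.offset,
        }


def _check_domain(y: np.ndarray, lam: float, outcome: str = "") -> None:
    strict = lam <= 0  # log and negative powers need y > 0
    bad = y <= 0 if strict else y < 0
    if np.any(bad):
        idx = np.where(bad)[0]
        raise TransformDomainError(
            f"{'non-positive' if strict else 'negative'} values for outcome {outcome or '<unnamed>'} "
            f"under lambda={lam}: indices {idx[:10].tolist()}{'...' if len(idx) > 10 else ''}"
        )


def apply_transform(y: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Elementwise strictly-increasing transform of raw scores."""
    y = np.asarray(y, dtype=float) + spec.offset
    _check_domain(y, spec.lam, spec.outcome)
    if spec.named_transform == "log":
        return np.log(y)
    if spec.named_transform == "sqrt":
        return np.sqrt(y)
    if spec.named_transform == "neg_inv_sqrt":
        return -1.0 / np.sqrt(y)
    if spec.named_transform == "identity":
        return y.copy()
    return special.boxcox(y, spec.lam)


def inverse_transform(t: np.ndarray, spec: TransformSpec) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if spec.named_transform == "log":
        y = np.exp(t)
    elif spec.named_transform == "sqrt":
        y = np.square(t)
    elif spec.named_transform == "neg_inv_sqrt":
        y = 1.0 / np.square(t)
    elif spec.named_transform == "identity":
        y = t.copy()
    else:
        y = special.inv_boxcox(t, spec.lam)
    return y - spec.offset


def _profile_loglik(y: np.ndarray, lam: float, X: np.ndarray, groups: np.ndarray, log_y_sum: float) -> float:
    t = special.boxcox(y, lam)
    ss = SufficientStats(X, t, groups, [f"x{j}" for j in range(X.shape[1])])
    fit = ss.fit(reml=False)
    return fit.loglik + (lam - 1.0) * log_y_sum


def select_boxcox_lambda(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    grid: Sequence[float] = _DEFAULT_GRID,
    snap_radius: float = 0.1,
    outcome: str = "",
    offset: float | None = None,
) -> TransformSpec:
    """Profile the Box-Cox power against the mixed-model likelihood.

    The criterion is the ML log-likelihood of the transformed response under
    the random-intercept model plus the Jacobian term
    ``(lambda - 1) * sum(log y)``.  The grid optimum is refined by bounded
    minimization between its neighbours and snapped to the nearest named
    power within ``snap_radius`` (interpretability is preferred over the
    raw optimum).  Exact zeros are handled by adding half the smallest
    positive observed value (or pass ``offset`` explicitly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be a (n, p) design aligned with y")
    grid = sorted(set(float(g) for g in grid) | set(NAMED_LAMBDAS.values()))
    if offset is None:
        offset = 0.0
        if np.any(y == 0):
            positive = y[y > 0]
            if positive.size == 0:
                raise TransformDomainError(f"outcome {outcome or '<unnamed>'} is identically zero")
            offset = 0.5 * float(positive.min())
    ys = y + offset
    if np.any(ys <= 0):
        raise TransformDomainError(
            f"non-positive values remain for outcome {outcome or '<unnamed>'} after offset {offset}"
        )
    log_y_sum = float(np.log(ys).sum())
    groups = np.asarray(groups)
    if groups.dtype.kind not in "iu":
        groups = pd.factorize(groups)[0]

    lls = [_profile_loglik(ys, lam, X, groups, log_y_sum) for lam in grid]
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda lam: -_profile_loglik(ys, lam, X, groups, log_y_sum),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-3},
        )
        lam_hat = float(res.x) if -res.fun >= lls[i] else float(grid[i])
    else:
        lam_hat = float(grid[i])

    named = None
    for name, lam0 in NAMED_LAMBDAS.items():
        if abs(lam_hat - lam0) <= snap_radius:
            named, lam_hat = name, lam0
            break
    return TransformSpec(outcome or "y", lam_hat, named, provenance="selected", offset=offset)


# ----------------------------------------------------------------------
# Rescaling for modelling
# ----------------------------------------------------------------------


@dataclass
class ScalingRecord:
    """Per-column centring/scaling applied before modelling (for
    back-conversion of coefficients to raw units)."""

    center: pd.Series
    scale: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.center, "scale": self.scale})


def rescale_for_modeling(
    frame: pd.DataFrame,
    continuous: Sequence[str] | None = None,
    binary: Sequence[str] | None = None,
    outcomes: Sequence[str] | None = None,
    transform_specs: dict[str, TransformSpec] | None = None,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Rescale a completed model frame for comparable coefficients.

    Continuous predictors: centred and divided by two standard deviations
    (computed within this dataset).  Binary predictors: left on 0/1 (their
    SD is roughly 0.5 unless highly skewed, so coefficients are already on
    a comparable per-two-SD scale).  Outcomes: transformed via
    ``transform_specs`` when given, then z-scored within the dataset.
    Raises ValueError naming any zero-variance predictor.
    """
    frame = frame.copy()
    if continuous is None:
        continuous = [t for t in schema.MODEL_TERMS if t not in schema.BINARY_TERMS and t in frame.columns]
    if binary is None:
        binary = [t for t in schema.BINARY_TERMS if t in frame.columns]
    if outcomes is None:
        outcomes = [o for o in schema.OUTCOMES if o in frame.columns]

    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for c in continuous:
        x = frame[c].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance predictor {c!r} cannot be rescaled")
        mu = float(x.mean())
        frame[c] = (x - mu) / (2.0 * sd)
        center[c], scale[c] = mu, 2.0 * sd
    for c in binary:
        center[c], scale[c] = 0.0, 1.0
    for o in outcomes:
        y = frame[o].to_numpy(dtype=float)
        if transform_specs and o in transform_specs:
            y = transform_specs[o].apply(y)
        mu, sd = float(y.mean()), float(np.std(y, ddof=1))
        if sd == 0.0:
            raise ValueError(f"outcome {o!r} has zero variance after transform")
        frame[o] = (y - mu) / sd
        center[o], scale[o] = mu, sd
    return frame, ScalingRecord(pd.Series(center), pd.Series(scale))
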