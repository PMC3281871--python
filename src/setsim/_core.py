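"""Compiled inner loop for the profiled random-intercept likelihood.

The bootstrap selection procedure performs hundreds of thousands of small
mixed-model fits; this module provides a numba-compiled evaluation of the
profiled deviance and a golden-section search over the variance ratio
``theta = tau^2 / sigma^2`` (on the log scale, with the ``theta = 0``
boundary checked explicitly).  When numba is unavailable the caller falls
back to the scipy implementation in :mod:`setsim.lmm`; results agree to the
optimizer tolerance.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_LOG2PI = 1.8378770664093453
_DEV_SINGULAR = 1e300


@njit(cache=True)
def _chol_lower(A):
    """Manual Cholesky; returns (L, ok). ok=False on a non-positive pivot."""
    p = A.shape[0]
    L = np.zeros((p, p))
    for i in range(p):
        s = A[i, i]
        for k in range(i):
            s -= L[i, k] * L[i, k]
        if s <= 1e-10 * (abs(A[i, i]) + 1.0):
            return L, False
        L[i, i] = np.sqrt(s)
        for j in range(i + 1, p):
            t = A[j, i]
            for k in range(i):
                t -= L[j, k] * L[i, k]
            L[j, i] = t / L[i, i]
    return L, True


@njit(cache=True)
def _profile_dev(theta, G, H, sizes, counts, n, reml):
    p1 = G.shape[0]
    p = p1 - 1
    A = G.copy()
    for s in range(sizes.shape[0]):
        c = theta / (1.0 + sizes[s] * theta)
        for i in range(p1):
            for j in range(p1):
                A[i, j] -= c * H[s, i, j]
    L, ok = _chol_lower(A[:p, :p].copy())
    if not ok:
        return _DEV_SINGULAR
    w = np.empty(p)
    for i in range(p):
        t = A[i, p]
        for k in range(i):
            t -= L[i, k] * w[k]
        w[i] = t / L[i, i]
    beta = np.empty(p)
    for i in range(p - 1, -1, -1):
        t = w[i]
        for k in range(i + 1, p):
            t -= L[k, i] * beta[k]
        beta[i] = t / L[i, i]
    rss = A[p, p]
    for i in range(p):
        rss -= A[i, p] * beta[i]
    if rss < 1e-12:
        rss = 1e-12
    logdet_v = 0.0
    for s in range(sizes.shape[0]):
        logdet_v += counts[s] * np.log1p(sizes[s] * theta)
    if reml:
        df = n - p
        dev = df * (_LOG2PI + 1.0 + np.log(rss / df)) + logdet_v
        for i in range(p):
            dev += 2.0 * np.log(L[i, i])
    else:
        dev = n * (_LOG2PI + 1.0 + np.log(rss / n)) + logdet_v
    return dev


@njit(cache=True)
def fit_theta(G, H, sizes, counts, n, reml):
    """Profiled variance-ratio estimate (0 allowed as a boundary optimum)."""
    best_u = -1e9  # log-theta; -inf stands for theta = 0
    best_d = _profile_dev(0.0, G, H, sizes, counts, n, reml)
    # coarse log-grid, then golden-section between the bracketing neighbours
    lo, hi = -8.0, 9.2
    ngrid = 12
    gi = -1
    for g in range(ngrid):
        u = lo + (hi - lo) * g / (ngrid - 1.0)
        d = _profile_dev(np.exp(u), G, H, sizes, counts, n, reml)
        if d < best_d:
            best_d, best_u, gi = d, u, g
    if gi < 0:
        return 0.0
    step = (hi - lo) / (ngrid - 1.0)
    a = best_u - step
    b = best_u + step
    invphi = 0.6180339887498949
    c = b - invphi * (b - a)
    e = a + invphi * (b - a)
    fc = _profile_dev(np.exp(c), G, H, sizes, counts, n, reml)
    fe = _profile_dev(np.exp(e), G, H, sizes, counts, n, reml)
    for _ in range(30):
        if fc < fe:
            b, e, fe = e, c, fc
            c = b - invphi * (b - a)
            fc = _profile_dev(np.exp(c), G, H, sizes, counts, n, reml)
        else:
            a, c, fc = c, e, fe
            e = a + invphi * (b - a)
            fe = _profile_dev(np.exp(e), G, H, sizes, counts, n, reml)
        if b - a < 1e-5:
            break
    u = 0.5 * (a + b)
    d = _profile_dev(np.exp(u), G, H, sizes, counts, n, reml)
    d0 = _profile_dev(0.0, G, H, sizes, counts, n, reml)
    if d0 <= d:
        return 0.0
    return np.exp(u)
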