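"""Numba-compiled scalar kernels for the KS objective's hot loop.

These duplicate, in scalar form, exactly the series and quadrature used by
:mod:`magdiff.wiener` (hybrid small-time images / large-time spectral series,
Gauss-Legendre convolution with the uniform non-decision window).  Parity
with the vectorised numpy implementation is asserted in the test suite; if
numba is unavailable the fitting code transparently falls back to numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


_SQRT2 = math.sqrt(2.0)
_TAU_CROSSOVER = 0.12
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# must match magdiff.wiener exactly
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


@njit(cache=False)
def _log_ndtr(x: float) -> float:
    if x > -20.0:
        return math.log(0.5 * math.erfc(-x / _SQRT2))
    xx = x * x
    return -0.5 * xx - _LOG_SQRT_2PI - math.log(-x) + math.log1p(-1.0 / xx + 3.0 / (xx * xx))


@njit(cache=False)
def _fpt_lower_cdf_scalar(t: float, a: float, v: float) -> float:
    if t <= 0.0:
        return 0.0
    tau = t / (a * a)
    if tau < _TAU_CROSSOVER:
        # images |k| <= 2 suffice below the crossover: the first neglected
        # image carries exp(-(5.5)^2 / (2 * 0.12)) ~ 1e-55 of mass
        sqrt_t = math.sqrt(t)
        acc = 0.0
        for k in range(-2, 3):
            c = a * (0.5 + 2.0 * k)
            s = 1.0 if c > 0.0 else -1.0
            acc += s * math.exp(-v * c + _log_ndtr(s * (v * t - c) / sqrt_t))
            acc += s * math.exp(v * c + _log_ndtr(-s * (v * t + c) / sqrt_t))
        val = math.exp(-v * a / 2.0) * acc
    else:
        p_low = 1.0 / (1.0 + math.exp(a * v))
        tail = 0.0
        for i in range(8):
            k = 2.0 * i + 1.0
            sgn = 1.0 if i % 2 == 0 else -1.0
            lam = 0.5 * (v * v + k * k * math.pi * math.pi / (a * a))
            term = k * math.exp(-lam * t) / lam
            tail += sgn * term
            if term < 1e-14:
                break
        val = p_low - math.pi / (a * a) * math.exp(-v * a / 2.0) * tail
    if val < 0.0:
        return 0.0
    if val > 1.0:
        return 1.0
    return val


@njit(cache=False)
def signed_cdf_points(
    x_sorted: np.ndarray,
    a: float,
    v: float,
    t0: float,
    st0: float,
    gl_nodes: np.ndarray,
    gl_weights: np.ndarray,
) -> np.ndarray:
    """Model signed-RT CDF at the given signed data points."""
    n = x_sorted.shape[0]
    out = np.empty(n)
    p_err = 1.0 / (1.0 + math.exp(a * v))
    for i in range(n):
        t = x_sorted[i]
        drift = v if t < 0.0 else -v
        tt = abs(t)
        if st0 < 1e-9:
            mass = _fpt_lower_cdf_scalar(tt - t0, a, drift)
        else:
            lo = tt - t0 - st0 / 2.0
            hi = tt - t0 + st0 / 2.0
            if lo < 0.0:
                lo = 0.0
            if hi < 0.0:
                hi = 0.0
            mid = 0.5 * (lo + hi)
            half = 0.5 * (hi - lo)
            acc = 0.0
            for j in range(gl_nodes.shape[0]):
                acc += gl_weights[j] * _fpt_lower_cdf_scalar(
                    mid + half * gl_nodes[j], a, drift
                )
            mass = half * acc / st0
        g = p_err - mass if t < 0.0 else p_err + mass
        if g < 0.0:
            g = 0.0
        if g > 1.0:
            g = 1.0
        out[i] = g
    return out


def ks_from_sorted(x_sorted: np.ndarray, a: float, v: float, t0: float, st0: float) -> float:
    """KS distance between model and empirical CDF of sorted signed times."""
    g = signed_cdf_points(x_sorted, a, v, t0, st0, _GL_NODES, _GL_WEIGHTS)
    n = len(x_sorted)
    steps_hi = np.arange(1, n + 1) / n
    steps_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(g - steps_hi)), np.max(np.abs(g - steps_lo))))


_PENALTY = 1.5


@njit(cache=False)
def _ks_objective(
    x: np.ndarray, x_sorted: np.ndarray, min_rt: float, gl_nodes: np.ndarray, gl_weights: np.ndarray
) -> float:
    a, v, t0, st0 = x[0], x[1], x[2], x[3]
    lo_support = t0 - st0 / 2.0
    if a <= 0.0 or t0 < 0.0 or st0 < 0.0 or lo_support < 0.0:
        m = a
        if t0 < m:
            m = t0
        if st0 < m:
            m = st0
        if lo_support < m:
            m = lo_support
        if m > 0.0:
            m = 0.0
        return _PENALTY + abs(m)
    if lo_support > min_rt:
        return _PENALTY + (lo_support - min_rt)
    g = signed_cdf_points(x_sorted, a, v, t0, st0, gl_nodes, gl_weights)
    n = x_sorted.shape[0]
    d = 0.0
    for i in range(n):
        hi = abs(g[i] - (i + 1.0) / n)
        lo = abs(g[i] - i / n)
        if hi > d:
            d = hi
        if lo > d:
            d = lo
    return d


@njit(cache=False)
def nelder_mead_ks(
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    x_sorted: np.ndarray,
    min_rt: float,
    maxfev: int,
    fatol: float,
    xatol: float,
    gl_nodes: np.ndarray,
    gl_weights: np.ndarray,
):
    """Nelder-Mead on the KS objective (scipy's constants and simplex init).

    Candidate points are clipped into the box bounds before evaluation.
    Returns (x_best, f_best, nfev, converged_flag).
    """
    ndim = 4
    rho, chi, psi, sigma = 1.0, 2.0, 0.5, 0.5
    nonzdelt, zdelt = 0.05, 0.00025

    sim = np.empty((ndim + 1, ndim))
    for j in range(ndim):
        sim[0, j] = min(max(x0[j], lower[j]), upper[j])
    for i in range(ndim):
        for j in range(ndim):
            sim[i + 1, j] = sim[0, j]
        if sim[0, i] != 0.0:
            sim[i + 1, i] = (1.0 + nonzdelt) * sim[0, i]
        else:
            sim[i + 1, i] = zdelt
        sim[i + 1, i] = min(max(sim[i + 1, i], lower[i]), upper[i])

    fsim = np.empty(ndim + 1)
    nfev = 0
    for i in range(ndim + 1):
        fsim[i] = _ks_objective(sim[i], x_sorted, min_rt, gl_nodes, gl_weights)
        nfev += 1

    order = np.argsort(fsim)
    sim = sim[order]
    fsim = fsim[order]

    xr = np.empty(ndim)
    xbar = np.empty(ndim)
    converged = False
    while nfev < maxfev:
        # convergence: simplex collapsed in both x and f
        fspread = 0.0
        xspread = 0.0
        for i in range(1, ndim + 1):
            df = abs(fsim[i] - fsim[0])
            if df > fspread:
                fspread = df
            for j in range(ndim):
                dx = abs(sim[i, j] - sim[0, j])
                if dx > xspread:
                    xspread = dx
        if fspread <= fatol and xspread <= xatol:
            converged = True
            break

        for j in range(ndim):
            s = 0.0
            for i in range(ndim):
                s += sim[i, j]
            xbar[j] = s / ndim

        for j in range(ndim):
            xr[j] = min(max((1.0 + rho) * xbar[j] - rho * sim[ndim, j], lower[j]), upper[j])
        fxr = _ks_objective(xr, x_sorted, min_rt, gl_nodes, gl_weights)
        nfev += 1

        shrink = False
        if fxr < fsim[0]:
            xe = np.empty(ndim)
            for j in range(ndim):
                xe[j] = min(
                    max((1.0 + rho * chi) * xbar[j] - rho * chi * sim[ndim, j], lower[j]),
                    upper[j],
                )
            fxe = _ks_objective(xe, x_sorted, min_rt, gl_nodes, gl_weights)
            nfev += 1
            if fxe < fxr:
                for j in range(ndim):
                    sim[ndim, j] = xe[j]
                fsim[ndim] = fxe
            else:
                for j in range(ndim):
                    sim[ndim, j] = xr[j]
                fsim[ndim] = fxr
        elif fxr < fsim[ndim - 1]:
            for j in range(ndim):
                sim[ndim, j] = xr[j]
            fsim[ndim] = fxr
        else:
            if fxr < fsim[ndim]:
                xc = np.empty(ndim)
                for j in range(ndim):
                    xc[j] = min(
                        max((1.0 + psi * rho) * xbar[j] - psi * rho * sim[ndim, j], lower[j]),
                        upper[j],
                    )
                fxc = _ks_objective(xc, x_sorted, min_rt, gl_nodes, gl_weights)
                nfev += 1
                if fxc <= fxr:
                    for j in range(ndim):
                        sim[ndim, j] = xc[j]
                    fsim[ndim] = fxc
                else:
                    shrink = True
            else:
                xcc = np.empty(ndim)
                for j in range(ndim):
                    xcc[j] = min(
                        max((1.0 - psi) * xbar[j] + psi * sim[ndim, j], lower[j]), upper[j]
                    )
                fxcc = _ks_objective(xcc, x_sorted, min_rt, gl_nodes, gl_weights)
                nfev += 1
                if fxcc < fsim[ndim]:
                    for j in range(ndim):
                        sim[ndim, j] = xcc[j]
                    fsim[ndim] = fxcc
                else:
                    shrink = True
            if shrink:
                for i in range(1, ndim + 1):
                    for j in range(ndim):
                        sim[i, j] = min(
                            max(
                                sim[0, j] + sigma * (sim[i, j] - sim[0, j]),
                                lower[j],
                            ),
                            upper[j],
                        )
                    fsim[i] = _ks_objective(sim[i], x_sorted, min_rt, gl_nodes, gl_weights)
                    nfev += 1

        order = np.argsort(fsim)
        sim = sim[order]
        fsim = fsim[order]

    return sim[0], fsim[0], nfev, converged
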