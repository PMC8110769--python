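"""The derivative-of-Gaussian (DoG) bias curve and its constrained fit.

Serial-dependence and adaptation biases in adjustment errors follow an odd,
bell-flanked curve of the history variable delta (previous minus present
orientation):

    error(delta) = delta * alpha * w * c * exp(-(w * delta)^2),
    c = sqrt(2) / exp(-1/2)

``alpha`` (degrees) is the amplitude: the curve peaks at exactly ``alpha``
at ``delta = 1 / (sqrt(2) w)``, so the constant ``c`` makes the amplitude
directly interpretable as the maximal predicted bias.  ``w`` (inverse
degrees) is the inverse curve width.  Positive ``alpha`` means attraction
toward the history item, negative means repulsion.

The fit minimizes the trial-level sum of squared residuals under box
constraints.  Because the model is linear in ``alpha`` at fixed ``w``, the
amplitude is profiled out in closed form (clipped to its bounds) and the
optimization reduces to a deterministic multi-start 1-D search over ``w``:
a coarse grid followed by bounded Brent refinement around every local
minimum of the grid profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: peak-normalizing constant sqrt(2)/e^{-1/2}
DOG_C = math.sqrt(2.0) * math.exp(0.5)

DEFAULT_ALPHA_BOUNDS = (-30.0, 30.0)   # degrees; brackets all plausible peaks
DEFAULT_W_BOUNDS = (0.005, 0.20)       # inverse degrees; peak delta ~3.5-141 deg
MIN_TRIALS = 20


def dog(delta, alpha, w):
    """Evaluate the DoG bias curve (odd in ``delta``; ``w`` must be > 0)."""
    if np.any(np.asarray(w) <= 0):
        raise ValueError("w must be strictly positive")
    delta = np.asarray(delta, dtype=float)
    out = delta * alpha * w * DOG_C * np.exp(-np.square(w * delta))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DoGFitResult:
    """Constrained least-squares DoG fit with derived peak metrics."""

    alpha: float          # amplitude, degrees (signed)
    w: float              # inverse width, 1/degrees
    sse: float            # sum of squared residuals at the optimum
    peak_delta: float     # delta of maximal |predicted error| = 1/(sqrt(2) w)
    peak_bias: float      # predicted error at +peak_delta = alpha
    peak_percent: float   # 100 * |peak_bias| / peak_delta
    n_trials: int
    converged: bool


def peak_metrics(alpha: float, w: float) -> tuple[float, float, float]:
    """Closed-form (peak_bias, peak_delta, peak_percent) of a DoG curve.

    The curve attains its extremum at ``delta = 1/(sqrt(2) w)`` where it
    equals ``alpha``; the percentage expresses the peak bias relative to
    the delta at which it occurs.
    """
    peak_delta = 1.0 / (math.sqrt(2.0) * w)
    peak_bias = float(alpha)
    peak_percent = 100.0 * abs(peak_bias) / peak_delta
    return peak_bias, peak_delta, peak_percent


def _profile(w, deltas, errors, sum_e2, alpha_bounds):
    """Optimal (clipped) alpha and sse at fixed w; vectorized over w."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    g = deltas[None, :] * w[:, None] * DOG_C * \
        np.exp(-np.square(w[:, None] * deltas[None, :]))
    num = g @ errors
    den = np.einsum("ij,ij->i", g, g)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    alpha = np.clip(alpha, *alpha_bounds)
    sse = sum_e2 - 2.0 * alpha * num + np.square(alpha) * den
    return alpha, sse


def fit_dog(deltas, errors,
            alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS,
            w_bounds: tuple[float, float] = DEFAULT_W_BOUNDS,
            n_grid: int = 25) -> DoGFitResult:
    """Constrained least-squares fit of the DoG curve to (delta, error) pairs.

    Trials with ``delta == 0`` or non-finite values are excluded (the model
    is identically zero at delta 0).  Fitting is deterministic; if every
    local refinement fails the best grid point is returned with
    ``converged=False`` rather than raising.
    """
    deltas = np.asarray(deltas, dtype=float).ravel()
    errors = np.asarray(errors, dtype=float).ravel()
    if deltas.shape != errors.shape:
        raise ValueError("deltas and errors must have the same length")
    ok = np.isfinite(deltas) & np.isfinite(errors) & (deltas != 0)
    deltas, errors = deltas[ok], errors[ok]
    n = len(deltas)
    if n == 0:
        raise ValueError("no usable (delta, error) pairs")
    if n < MIN_TRIALS:
        logger.warning("fitting DoG on only %d trials (< %d); estimates will "
                       "be unstable", n, MIN_TRIALS)
    sum_e2 = float(errors @ errors)

    ws = np.geomspace(w_bounds[0], w_bounds[1], n_grid)
    alphas, sses = _profile(ws, deltas, errors, sum_e2, alpha_bounds)

    # refine every local minimum of the grid profile with bounded Brent
    best = (float(sses.min()), float(alphas[int(np.argmin(sses))]),
            float(ws[int(np.argmin(sses))]))
    converged = False
    for i in range(n_grid):
        left = sses[i - 1] if i > 0 else np.inf
        right = sses[i + 1] if i < n_grid - 1 else np.inf
        if not (sses[i] <= left and sses[i] <= right):
            continue
        lo = ws[max(i - 1, 0)]
        hi = ws[min(i + 1, n_grid - 1)]
        if lo == hi:
            converged = True
            continue
        res = minimize_scalar(
            lambda w: float(_profile(w, deltas, errors, sum_e2, alpha_bounds)[1][0]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        if res.success:
            converged = True
            if res.fun < best[0]:
                a, _ = _profile(res.x, deltas, errors, sum_e2, alpha_bounds)
                best = (float(res.fun), float(a[0]), float(res.x))
    sse, alpha, w = best
    peak_bias, peak_delta, peak_percent = peak_metrics(alpha, w)
    return DoGFitResult(alpha=alpha, w=w, sse=max(sse, 0.0),
                        peak_delta=peak_delta, peak_bias=peak_bias,
                        peak_percent=peak_percent, n_trials=n,
                        converged=converged)


def grid_search_dog(deltas, errors,
                    alpha_bounds=DEFAULT_ALPHA_BOUNDS,
                    w_bounds=DEFAULT_W_BOUNDS,
                    n_alpha: int = 201, n_w: int = 201) -> tuple[float, float, float]:
    """Dense exhaustive (alpha, w) grid search; the slow reference optimum.

    Returns ``(alpha, w, sse)`` of the best grid point.  Used as an
    independent cross-check of :func:`fit_dog` on small inputs.
    """
    deltas = np.asarray(deltas, dtype=float).ravel()
    errors = np.asarray(errors, dtype=float).ravel()
    ok = np.isfinite(deltas) & np.isfinite(errors) & (deltas != 0)
    deltas, errors = deltas[ok], errors[ok]
    alphas = np.linspace(alpha_bounds[0], alpha_bounds[1], n_alpha)
    ws = np.geomspace(w_bounds[0], w_bounds[1], n_w)
    best = (math.inf, math.nan, math.nan)
    for w in ws:
        g = deltas * w * DOG_C * np.exp(-np.square(w * deltas))
        resid = errors[None, :] - alphas[:, None] * g[None, :]
        sse = np.einsum("ij,ij->i", resid, resid)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(alphas[i]), float(w))
    return best[1], best[2], best[0]
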