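"""Weibull 2AFC performance function: evaluation and least-squares fitting.

The performance function is

    P(c) = 1 - 0.5 * exp(-(c / alpha) ** beta)

with *c* the stimulus contrast (%), *alpha* the contrast supporting
threshold performance (82% correct; exactly 1 - 0.5/e) and *beta* the slope.
The same function serves psychometric data (proportion correct) and
neurometric data (ROC area vs contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: Fitting bounds. A threshold is a contrast, so alpha is capped at 100%:
#: cells or pools that never reach 82% correct within the physical contrast
#: range are reported at the ceiling (and flagged unconverged). Beta covers
#: realistic slopes.
ALPHA_BOUNDS = (0.5, 100.0)
BETA_BOUNDS = (0.3, 8.0)

_ALPHA_GRID = np.geomspace(*ALPHA_BOUNDS, 48)
_BETA_GRID = np.geomspace(*BETA_BOUNDS, 24)


@dataclass(frozen=True)
class WeibullFit:
    """Fitted (alpha, beta) with the residual sum of squares.

    ``converged`` is False for degenerate data (e.g. a pool at chance at
    every contrast), in which case alpha is pinned at the upper bound.
    """

    alpha: float
    beta: float
    fit_error: float
    converged: bool = True

    @property
    def threshold(self) -> float:
        return self.alpha

    @property
    def slope(self) -> float:
        return self.beta


def weibull_eval(fit: WeibullFit | tuple[float, float], c) -> np.ndarray | float:
    """Evaluate the Weibull performance function at contrast(s) ``c``.

    Returns 0.5 at c = 0 and 1 - 0.5/e (~0.8161) at c = alpha; strictly
    increasing in c. Negative contrasts are a domain error.
    """
    alpha, beta = (fit.alpha, fit.beta) if isinstance(fit, WeibullFit) else fit
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("contrast must be non-negative")
    out = 1.0 - 0.5 * np.exp(-((c_arr / alpha) ** beta))
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def _sse_grid(c: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Best (alpha, beta) on the fixed multi-start grid."""
    # (nA, nB, nC) model surface; small enough to hold in memory
    model = 1.0 - 0.5 * np.exp(
        -((c[None, None, :] / _ALPHA_GRID[:, None, None]) ** _BETA_GRID[None, :, None])
    )
    sse = ((model - p[None, None, :]) ** 2).sum(axis=-1)
    ia, ib = np.unravel_index(np.argmin(sse), sse.shape)
    return float(_ALPHA_GRID[ia]), float(_BETA_GRID[ib])


def fit_weibull(
    contrasts, prop_correct, trials_per_point: int | None = None
) -> WeibullFit:
    """Least-squares Weibull fit to (contrast, proportion-correct) points.

    Blank (0%) points are dropped: the function is pinned to 0.5 there for
    every parameter value, so they carry no information. Fitting is a fixed
    coarse grid over bounded (alpha, beta) followed by bounded local
    refinement, hence deterministic. Data that never rise above chance yield
    an unconverged fit with alpha at the upper bound rather than an
    exception, so parameter sweeps tolerate insensitive pools.
    """
    c = np.asarray(contrasts, dtype=float)
    p = np.asarray(prop_correct, dtype=float)
    if c.shape != p.shape:
        raise ValueError("contrasts and prop_correct must have the same length")
    nz = c > 0
    c, p = c[nz], p[nz]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct non-zero contrasts")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")

    if np.all(p <= 0.5 + 1e-9):
        return WeibullFit(ALPHA_BOUNDS[1], 1.0, float(((p - 0.5) ** 2).sum()), False)

    x0 = np.array(_sse_grid(c, p))

    def resid(x):
        return 1.0 - 0.5 * np.exp(-((c / x[0]) ** x[1])) - p

    sol = least_squares(
        resid,
        x0,
        bounds=([ALPHA_BOUNDS[0], BETA_BOUNDS[0]], [ALPHA_BOUNDS[1], BETA_BOUNDS[1]]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    alpha, beta = float(sol.x[0]), float(sol.x[1])
    err = float((sol.fun**2).sum())
    # An alpha pressed against the upper bound, or data that never rise
    # meaningfully above chance, cannot constrain the threshold
    # (insensitive pool / extrapolation failure).
    converged = alpha < 0.999 * ALPHA_BOUNDS[1] and float(p.max()) > 0.55
    return WeibullFit(alpha, beta, err, converged)
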