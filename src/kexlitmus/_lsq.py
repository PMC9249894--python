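"""Internal weighted nonlinear least-squares helper.

Positive parameters are optimized on a log scale (positivity without
penalty terms, robust across decades) from several starting points; the
reported point estimate is the best minimum.  Parameter uncertainties are
computed in the *linear* parameter space from the residual-scaled
covariance s^2 (J^T J)^-1 with s^2 = wSSE/(n - p) — the standard variance
estimator for weighted fits — so that sigma reflects the local curvature
of the likelihood in the units of the parameter, not of its logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["LsqResult", "fit_multistart"]


@dataclass
class LsqResult:
    x: np.ndarray          # linear-space parameter estimates
    sigma: np.ndarray      # linear-space standard errors
    wsse: float
    chi2_red: float
    success: bool
    message: str = ""


def _linear_jacobian(residuals, x: np.ndarray) -> np.ndarray:
    n = len(residuals(x))
    J = np.empty((n, x.size))
    for j in range(x.size):
        h = 1e-6 * max(abs(x[j]), 1e-12)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (residuals(xp) - residuals(xm)) / (2.0 * h)
    return J


def fit_multistart(
    residuals,
    starts: list[np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    max_nfev: int = 10_000,
) -> LsqResult:
    """Minimize ||residuals(x)||^2 over positive parameters.

    ``residuals`` maps a linear-space parameter vector to the weighted
    residual vector; ``starts`` are linear-space starting points clipped
    into [lower, upper].
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    log_lo, log_hi = np.log(lower), np.log(upper)

    def z_residuals(z):
        return residuals(np.exp(z))

    best = None
    for x0 in starts:
        z0 = np.clip(np.log(np.clip(x0, lower, upper)), log_lo, log_hi)
        try:
            res = least_squares(
                z_residuals, z0, bounds=(log_lo, log_hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        nan = np.full(lower.size, np.nan)
        return LsqResult(nan, nan, math.nan, math.nan, False, "no start converged")

    x = np.exp(best.x)
    wsse = 2.0 * best.cost
    n = len(best.fun)
    p = x.size
    dof = max(n - p, 1)
    s2 = wsse / dof
    J = _linear_jacobian(residuals, x)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        sigma = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        sigma = np.full(p, np.nan)
    return LsqResult(x, sigma, wsse, wsse / dof, True, best.message)
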