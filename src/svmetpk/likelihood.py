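"""Per-observation likelihood under the double-exponential error model with
M3 handling of censored (below-LLOQ) observations.

Data are fitted on the log scale.  For a prediction f with error offset m,

    mu  = ln(f + m)
    w^2 = (f/(f+m))^2 * var1(phase) + (m/(f+m))^2 * var2

A quantified observation contributes the Normal log-density of ln(dv) at
(mu, w^2); a censored observation contributes ln Phi((ln lloq - mu)/w), the
log-probability that the model indeed predicts a value below the limit.

Objective-function values follow the NONMEM convention: the -0.5*ln(2*pi)
constant of each non-censored observation is dropped, so differences are
directly comparable to chi-squared quantiles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import log_ndtr

from .params import ResidualSpec

LOG_2PI = math.log(2.0 * math.pi)


def error_moments(f, m, var1, var2):
    """Log-scale mean ``mu`` and variance ``w2`` of an observation."""
    f = np.asarray(f, dtype=float)
    fm = f + m
    if np.any(fm <= 0):
        raise ValueError("f + m must be positive")
    w1 = f / fm
    w2c = m / fm
    mu = np.log(fm)
    w2 = w1 * w1 * np.asarray(var1) + w2c * w2c * var2
    return mu, w2


def observation_loglik(dv, blq, lloq, f, spec: ResidualSpec, time) -> float:
    """Log-likelihood contribution of one observation row.

    ``dv`` may be None/NaN for a censored row (``blq`` True).  Includes the
    full Normal constant; the estimation engine applies the NONMEM offset
    separately.
    """
    if f < 0:
        raise ValueError("prediction must be non-negative")
    mu, w2 = error_moments(f, spec.m, float(spec.var1(time)), spec.var2)
    if blq:
        if w2 <= 0:
            # degenerate error: censoring is certain iff mu < ln lloq
            return 0.0 if mu < math.log(lloq) else -np.inf
        return float(log_ndtr((math.log(lloq) - mu) / math.sqrt(w2)))
    if dv is None or (isinstance(dv, float) and math.isnan(dv)):
        raise ValueError("non-censored observation requires dv")
    if dv <= 0:
        raise ValueError("dv must be positive")
    if w2 <= 0:
        raise ValueError("zero residual variance with observed data")
    z = math.log(dv) - mu
    return float(-0.5 * (LOG_2PI + math.log(w2) + z * z / w2))


def row_nll_moments(logdv, blq, loglloq, mu, w2):
    """Vectorised negative log-likelihood per row from the log-scale
    moments, NONMEM constant convention (no 2*pi term on non-censored
    rows).  ``logdv`` is ignored (may be NaN) where ``blq`` is True."""
    blq = np.asarray(blq, dtype=bool)
    w2 = np.maximum(w2, 1e-300)
    w = np.sqrt(w2)
    z = np.where(blq, 0.0, np.nan_to_num(logdv) - mu)
    nll_obs = 0.5 * (np.log(w2) + z * z / w2)
    nll_cens = -log_ndtr((loglloq - mu) / w)
    return np.where(blq, nll_cens, nll_obs)


def row_nll(logdv, blq, loglloq, f, m, var1, var2):
    """As :func:`row_nll_moments`, from predictions and error parameters."""
    mu, w2 = error_moments(f, m, var1, var2)
    return row_nll_moments(logdv, blq, loglloq, mu, w2)


def censored_curvature(loglloq, mu, w2):
    """Second derivative of -ln Phi((ln lloq - mu)/w) with respect to mu:
    h(z)(z + h(z))/w^2 with h the Normal hazard, evaluated stably."""
    w2 = np.maximum(w2, 1e-300)
    w = np.sqrt(w2)
    z = (loglloq - mu) / w
    # hazard phi(z)/Phi(z) via logs; for very negative z use the asymptote
    logh = -0.5 * (z * z + LOG_2PI) - log_ndtr(z)
    h = np.where(z < -30.0, -z, np.exp(np.minimum(logh, 700.0)))
    return h * (z + h) / w2
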