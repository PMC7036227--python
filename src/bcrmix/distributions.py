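"""Count-leaf distributions: zero-truncated negative binomial and
discretized generalized Pareto.

Both are computed in log space and vectorized over integer count arrays.
The negative binomial is parametrized by mean ``mu`` and dispersion ``r``
(variance mu + mu^2/r); the generalized Pareto is discretized by CDF
differencing on unit intervals, shifted to integer support {u, u+1, ...}.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .params import GenParetoParams, NegBinParams


def _log1mexp(a):
    """log(1 - exp(a)) for a < 0, numerically stable."""
    a = np.asarray(a, dtype=float)
    out = np.where(
        a < -np.log(2.0),
        np.log1p(-np.exp(np.minimum(a, -1e-300))),
        np.log(-np.expm1(np.maximum(a, -745.0))),
    )
    return out


def _logdiffexp(a, b):
    """log(exp(a) - exp(b)) for a >= b."""
    with np.errstate(invalid="ignore"):
        out = a + _log1mexp(np.minimum(b - a, 0.0))
    # exact ties (both -inf, or equal) carry zero mass
    return np.where(b >= a, -np.inf, out)


def log_pmf_ztnb(x, mu: float, r: float):
    """Log pmf of the zero-truncated negative binomial on {1, 2, ...}.

    log[ NB(x; mu, r) / (1 - NB(0; mu, r)) ].
    """
    x = np.asarray(x)
    if np.any(x < 1):
        raise ValueError("zero-truncated negative binomial support is x >= 1")
    if not (mu > 0 and r > 0):
        raise ValueError("mu and r must be positive")
    p = r / (r + mu)
    log_p0 = r * np.log(p)  # NB(0) = p^r
    return stats.nbinom.logpmf(x, r, p) - _log1mexp(log_p0)


def log_pmf_dgpd(x, xi: float, sigma: float, u: int = 1):
    """Log pmf of the discretized generalized Pareto on {u, u+1, ...}.

    pmf(x) = F(x - u + 1) - F(x - u) with F the continuous GPD CDF
    (shape xi, scale sigma, location 0); computed via survival functions.
    """
    x = np.asarray(x)
    GenParetoParams(xi, sigma, u).validate()
    if np.any(x < u):
        raise ValueError(f"discretized generalized Pareto support is x >= u = {u}")
    y = np.asarray(x - u, dtype=float)
    logsf0 = stats.genpareto.logsf(y, xi, scale=sigma)
    logsf1 = stats.genpareto.logsf(y + 1.0, xi, scale=sigma)
    return _logdiffexp(logsf0, logsf1)


def sample_ztnb(n: int, mu: float, r: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` zero-truncated negative binomial counts by rejection of zeros."""
    NegBinParams(mu, r).validate()
    p = r / (r + mu)
    out = rng.negative_binomial(r, p, size=n)
    bad = out == 0
    while np.any(bad):
        out[bad] = rng.negative_binomial(r, p, size=int(bad.sum()))
        bad = out == 0
    return out.astype(np.int64)


def sample_dgpd(n: int, xi: float, sigma: float, u: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` discretized generalized Pareto counts: u + floor(Y) with Y
    continuous GPD, which has exactly the CDF-differenced pmf."""
    GenParetoParams(xi, sigma, u).validate()
    v = rng.random(n)  # survival-function inversion: Y = sigma/xi ((v)^-xi - 1)
    if abs(xi) < 1e-12:
        y = -sigma * np.log(v)
    else:
        y = sigma / xi * (v ** (-xi) - 1.0)
    return (u + np.floor(y)).astype(np.int64)
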