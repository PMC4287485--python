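"""Beta-binomial distribution fitting.

The read counts at a cytosine are modelled as beta-binomial: the per-site
methylation rate is drawn from a Beta(alpha, beta) and the number of
methylation-supporting reads is binomial given that rate.  This compound
model captures the overdispersion of bisulfite read counts relative to a
plain binomial and is the emission model of the segmentation HMM as well
as the likelihood of the differential-methylation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln

# Bounds on log(alpha), log(beta) during optimisation.  The lower bound is
# hit by degenerate data (e.g. all-zero counts); it pins mu near 0 or 1.
# The upper bound imposes a dispersion floor: per-cytosine methylation
# rates always retain residual biological and technical spread, so the
# beta-binomial is never allowed to collapse to a pure binomial.  This
# also regularises maximum-likelihood fits on small regions, whose
# likelihood-ratio statistics would otherwise be inflated by precision
# estimates diverging at the boundary.
_LOG_BOUND = (np.log(1e-4), np.log(25.0))


@dataclass(frozen=True)
class BetaBinomParams:
    """Parameters (alpha, beta) of a beta-binomial distribution."""

    alpha: float
    beta: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")

    @property
    def mu(self) -> float:
        """Mean of the underlying Beta rate distribution."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def sigma(self) -> float:
        """Standard deviation of the underlying Beta rate distribution."""
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))


def betabinom_logpmf(x, n, alpha: float, beta: float):
    """Vectorised beta-binomial log pmf.

    Positions with ``n == 0`` contribute log-probability 0 (an uncovered
    site carries no information).
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    out = (
        gammaln(n + 1.0)
        - gammaln(x + 1.0)
        - gammaln(n - x + 1.0)
        + betaln(x + alpha, n - x + beta)
        - betaln(alpha, beta)
    )
    return np.where(n > 0, out, 0.0)


def loglik(x, n, alpha: float, beta: float, weights=None) -> float:
    """Total (optionally weighted) beta-binomial log-likelihood."""
    ll = betabinom_logpmf(x, n, alpha, beta)
    if weights is not None:
        ll = ll * weights
    return float(np.sum(ll))


def _negloglik_and_grad(theta, x, n, w):
    a, b = np.exp(theta)
    ll = (
        betaln(x + a, n - x + b) - betaln(a, b)
    )  # binomial coefficient constant dropped
    da = digamma(x + a) - digamma(n + a + b) - digamma(a) + digamma(a + b)
    db = digamma(n - x + b) - digamma(n + a + b) - digamma(b) + digamma(a + b)
    if w is not None:
        ll = ll * w
        da = da * w
        db = db * w
    # chain rule for log-parameters
    grad = -np.array([np.sum(da) * a, np.sum(db) * b])
    return -float(np.sum(ll)), grad


def _moment_init(x, n, w):
    if w is None:
        w = np.ones_like(x, dtype=float)
    rates = x / n
    m = np.average(rates, weights=w)
    v = np.average((rates - m) ** 2, weights=w)
    m = min(max(m, 1e-3), 1.0 - 1e-3)
    v = max(v, 1e-4)
    # method-of-moments for the Beta rate distribution, ignoring binomial noise
    nu = m * (1.0 - m) / v - 1.0
    nu = min(max(nu, 0.1), 1e3)
    theta = np.log(np.array([m * nu, (1.0 - m) * nu]))
    return np.clip(theta, _LOG_BOUND[0], _LOG_BOUND[1])


def fit_betabinom_mle(counts, weights=None) -> BetaBinomParams:
    """Maximum-likelihood beta-binomial fit to (meth, total) count pairs.

    Parameters
    ----------
    counts
        Sequence of ``(meth_reads, total_reads)`` pairs, or a 2-column
        array.  Pairs with ``total_reads == 0`` are ignored.
    weights
        Optional per-observation non-negative weights (used by the HMM
        M-step, where observations are weighted by state posteriors).

    The optimiser works on (log alpha, log beta) with analytic gradients;
    all-zero (or all-full) count data drive a parameter to its lower
    bound, pinning the mean near the boundary.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 2)
    x, n = arr[:, 0], arr[:, 1]
    keep = n > 0
    if not np.any(keep):
        raise ValueError("need at least one observation with total_reads > 0")
    x, n = x[keep], n[keep]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
        if np.sum(w) <= 0:
            raise ValueError("weights sum to zero")
    if np.any(x > n) or np.any(x < 0):
        raise ValueError("meth_reads must lie in [0, total_reads]")

    theta0 = _moment_init(x, n, w)
    res = minimize(
        _negloglik_and_grad,
        theta0,
        args=(x, n, w),
        jac=True,
        method="L-BFGS-B",
        bounds=[_LOG_BOUND, _LOG_BOUND],
    )
    a, b = np.exp(res.x)
    return BetaBinomParams(alpha=float(a), beta=float(b), converged=bool(res.success))
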