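"""Multiple-testing correction: Storey q-values.

q-values are computed from the sorted p-value vector with an estimate of
the null proportion pi0 obtained on a lambda grid (0.05, 0.10, ..., 0.95)
and smoothed with a cubic spline evaluated at the largest lambda.  With
few tests the pi0 estimate is unstable, so pi0 falls back to 1 (which
makes the q-values coincide with Benjamini-Hochberg).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import UnivariateSpline

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p_values) -> float:
    """Estimate the proportion of true null hypotheses."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in _LAMBDA_GRID])
    try:
        spline = UnivariateSpline(_LAMBDA_GRID, pi0_l, k=3)
        pi0 = float(spline(_LAMBDA_GRID[-1]))
    except Exception:
        pi0 = float(pi0_l[-1])
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a vector of p-values.

    Ties are handled by stable sorting; the returned q-values are
    monotone non-decreasing in p and bounded by 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p-value downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
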