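"""Upper-tail probabilities of positively weighted sums of 1-df chi-squares.

The null distribution of the HEIDI heterogeneity statistic is
Q = sum_i w_i * chi2_1i with the w_i the eigenvalues of the correlation
matrix of the per-instrument deviation z-scores.  The default evaluator is
Ruben's exact mixture-of-chi-squares series, which converges for strictly
positive weights with a computable truncation bound; the Liu–Tang–Zhang
moment-matching approximation is available as a fast alternative.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, ncx2

__all__ = ["weighted_chisq_tail"]


def _ruben_tail(weights: np.ndarray, q: float, tol: float = 1e-12, max_terms: int = 20000) -> float:
    """Ruben's series: Q/beta is a mixture of central chi-squares with
    df = n, n+2, n+4, ...; mixing weights a_k sum to one, so the truncation
    error is bounded by the untouched mixing mass."""
    lam = weights
    n = lam.size
    beta = 0.90625 * lam.min()
    ratio = 1.0 - beta / lam  # in [0, 1)
    a = np.empty(max_terms)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / lam)))
    g = np.empty(max_terms)
    cum = a[0]
    k_used = 1
    for k in range(1, max_terms):
        g[k] = 0.5 * float(np.sum(ratio**k))
        a[k] = float(np.dot(g[1 : k + 1][::-1], a[:k])) / k
        cum += a[k]
        k_used = k + 1
        if 1.0 - cum < tol:
            break
    ks = np.arange(k_used)
    cdf_terms = chi2.cdf(q / beta, df=n + 2 * ks)
    cdf = float(np.dot(a[:k_used], cdf_terms))
    # remaining mixture mass could lie entirely in either tail
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def _ltz_tail(weights: np.ndarray, q: float) -> float:
    """Liu–Tang–Zhang: match skewness/kurtosis with a (non)central chi-square."""
    c1 = weights.sum()
    c2 = (weights**2).sum()
    c3 = (weights**3).sum()
    c4 = (weights**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    t_star = (q - c1) / np.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = c2**3 / c3**2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(x, df, delta))
    return float(chi2.sf(x, df))


def weighted_chisq_tail(weights, q: float, method: str = "ruben") -> float:
    """P(sum_i w_i * chi2_1 > q) for positive weights w.

    Parameters
    ----------
    weights : array-like of positive reals
    q : non-negative statistic value
    method : "ruben" (exact series, default) or "ltz" (Liu–Tang–Zhang
        moment matching).
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("weights must be non-empty")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0.0:
        return 1.0
    if w.size == 1:
        return float(chi2.sf(q / w[0], df=1))
    if method == "ruben":
        p = _ruben_tail(w, float(q))
    elif method == "ltz":
        p = _ltz_tail(w, float(q))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(1.0, max(p, 1e-300)))
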