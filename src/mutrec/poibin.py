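"""Poisson-binomial tail probabilities.

The number of tumors carrying at least one mutation in a region is a sum of
independent, non-identically distributed Bernoulli variables (one success
probability p_i per tumor), i.e. Poisson-binomial. Recurrence significance is
the upper tail Pr(K >= k).

Two routes are provided:

* :func:`tail_exact` — exact dynamic-programming convolution of the PMF,
  truncated at k (O(n*k)); used for every reported p-value.
* :func:`tail_rna` — refined normal approximation with a skewness
  (Cornish–Fisher style) correction and continuity correction; cheap enough
  to prefilter millions of candidate regions.
"""

from __future__ import annotations

import numpy as np


def _validate(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D array of probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("success probabilities must lie in [0, 1]")
    return p


def pmf(p) -> np.ndarray:
    """Full PMF of the Poisson-binomial distribution (length n+1)."""
    p = _validate(p)
    dist = np.ones(1)
    for pi in p:
        new = np.empty(len(dist) + 1)
        new[0] = dist[0] * (1 - pi)
        new[1:-1] = dist[1:] * (1 - pi) + dist[:-1] * pi
        new[-1] = dist[-1] * pi
        dist = new
    return dist


def tail_exact(p, k: int) -> float:
    """Exact Pr(K >= k) by truncated DP convolution.

    Only the first k+1 PMF cells are tracked (counts >= k are pooled), so the
    cost is O(n * k). Returns 1 for k <= 0 and 0 for k > n.
    """
    p = _validate(p)
    n = len(p)
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    # dist[j] = Pr(K_so_far == j) for j < k; tail accumulates Pr(K_so_far >= k)
    dist = np.zeros(k)
    dist[0] = 1.0
    tail = 0.0
    for pi in p:
        shifted = dist * pi
        tail += shifted[-1]
        dist *= 1 - pi
        dist[1:] += shifted[:-1]
    return float(min(1.0, tail))


def tail_rna(p, k: int) -> float:
    """Refined normal approximation to Pr(K >= k).

    CDF(x) ~ Phi(z) + gamma * (1 - z^2) * phi(z) / 6 with z the continuity-
    corrected standardized count and gamma the distribution skewness. Falls
    back to the exact DP when the variance is degenerate (all p in {0, 1}).
    """
    from scipy.stats import norm

    p = _validate(p)
    n = len(p)
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    mu = float(p.sum())
    var = float((p * (1 - p)).sum())
    if var <= 0:
        return tail_exact(p, k)
    sigma = np.sqrt(var)
    gamma = float((p * (1 - p) * (1 - 2 * p)).sum()) / (sigma**3)
    z = (k - 0.5 - mu) / sigma  # Pr(K >= k) = 1 - CDF(k - 1), continuity-corrected
    cdf = norm.cdf(z) + gamma * (1 - z * z) * norm.pdf(z) / 6.0
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def randomized_pvalue(p, k: int, u: float) -> float:
    """Uniformized p-value Pr(K >= k+1) + u * Pr(K = k).

    Exactly Uniform(0, 1) under the null for u ~ Uniform(0, 1); used only for
    calibration diagnostics of the discrete test, never for reported results.
    """
    upper = tail_exact(p, k + 1)
    point = tail_exact(p, k) - upper
    return float(upper + u * point)
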