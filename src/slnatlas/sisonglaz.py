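"""Sison-Glaz (1995) simultaneous confidence intervals for multinomial proportions.

Given counts ``n_1..n_k`` with total ``N``, the procedure approximates the
simultaneous coverage

    nu(c) = P(n_i - c <= X_i <= n_i + c for all i),   X ~ Multinomial(N, n/N)

by representing the multinomial as independent Poissons conditioned on their
sum: ``nu(c)`` is the product of truncated-Poisson cell probabilities times an
Edgeworth (fourth-order) approximation to the conditional density of the sum
at ``N``.  The interval half-width is the largest integer ``c`` with
``nu(c) <= 1 - alpha``, refined by linear interpolation: with
``gamma = (1 - alpha - nu(c)) / (nu(c+1) - nu(c))`` the intervals are

    [ p_i - c/N,  p_i + c/N + 2*gamma/N ]   clamped to [0, 1].

All k intervals share the same pre-clamp width.  No installed package
provides this procedure, so it is implemented here from the published
algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["sison_glaz_intervals"]


def _truncated_poisson_cumulants(c: int, lam: np.ndarray):
    """First four central moments and mass of Poisson(lam) truncated to
    [lam - c, lam + c], vectorized over lam (= the observed counts)."""
    lam = np.asarray(lam, dtype=float)
    a = lam + c
    b = np.maximum(lam - c, 0.0)
    den = stats.poisson.cdf(a, lam) - stats.poisson.cdf(b - 1, lam)
    den = np.where(lam > 0, den, 1.0)
    mu = []
    for r in range(1, 5):
        pois_a = np.where(
            a - r >= 0,
            stats.poisson.cdf(a, lam) - stats.poisson.cdf(a - r, lam),
            stats.poisson.cdf(a, lam),
        )
        pois_b = np.where(
            b - r - 1 >= 0,
            stats.poisson.cdf(b - 1, lam) - stats.poisson.cdf(b - r - 1, lam),
            np.where(b - 1 >= 0, stats.poisson.cdf(b - 1, lam), 0.0),
        )
        mu.append(lam**r * (1.0 - (pois_a - pois_b) / den))
    m1, m2, m3, m4 = mu
    c1 = m1
    c2 = m2 + m1 - m1**2
    c3 = m3 + m2 * (3 - 3 * m1) + (m1 - 3 * m1**2 + 2 * m1**3)
    c4 = (
        m4
        + m3 * (6 - 4 * m1)
        + m2 * (7 - 12 * m1 + 6 * m1**2)
        + m1
        - 4 * m1**2
        + 6 * m1**3
        - 3 * m1**4
    )
    return c1, c2, c3, c4, den


def _coverage(c: int, counts: np.ndarray) -> float:
    """Edgeworth-corrected truncated-product approximation of nu(c)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    c1, c2, c3, c4, den = _truncated_poisson_cumulants(c, counts)
    s1, s2 = c1.sum(), c2.sum()
    s3 = c3.sum()
    s4 = (c4 - 3 * c2**2).sum()
    prob_n = 1.0 / (stats.poisson.cdf(n, n) - stats.poisson.cdf(n - 1, n))
    z = (n - s1) / np.sqrt(s2)
    g1 = s3 / s2**1.5
    g2 = s4 / s2**2
    poly = (
        1.0
        + g1 * (z**3 - 3 * z) / 6.0
        + g2 * (z**4 - 6 * z**2 + 3) / 24.0
        + g1**2 * (z**6 - 15 * z**4 + 45 * z**2 - 15) / 72.0
    )
    f = poly * np.exp(-z * z / 2.0) / np.sqrt(2.0 * np.pi)
    return float(np.prod(den) * prob_n * f / np.sqrt(s2))


def sison_glaz_intervals(
    counts, level: float = 0.95, c_start: int = 1
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Simultaneous ``level`` confidence intervals for multinomial proportions.

    Parameters
    ----------
    counts
        Non-negative integer category counts with positive total.
    level
        Simultaneous confidence level in (0, 1).
    c_start
        Lower bound for the half-width search (warm start for repeated calls;
        the search backtracks if the start already exceeds the level).

    Returns
    -------
    (lower, upper, c, gamma)
        Per-category clamped bounds plus the integer half-width ``c`` and the
        interpolation constant ``gamma`` in [0, 1).
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("total count must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")

    cc = max(int(c_start), 1)
    while cc > 1 and _coverage(cc - 1, counts) > level:
        cc -= 1
    nu_prev = _coverage(cc - 1, counts) if cc > 1 else 0.0
    while True:
        nu_cc = _coverage(cc, counts)
        if nu_cc > level >= nu_prev:
            break
        if cc >= n:
            break
        nu_prev = nu_cc
        cc += 1
    c = cc - 1
    gamma = (level - nu_prev) / (nu_cc - nu_prev)

    p = counts / n
    lower = np.maximum(0.0, p - c / n)
    upper = np.minimum(1.0, p + c / n + 2.0 * gamma / n)
    return lower, upper, c, float(gamma)
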