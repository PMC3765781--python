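"""Independent brute-force oracles used to freeze expected values.

Each oracle re-derives a statistic from its textbook definition by direct
enumeration or loops, deliberately avoiding the code paths (vectorization,
log-space, library calls) used by the implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import binom, nbinom


def fisher_p_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric point
    probabilities <= the observed one, enumerated over the margin-fixed
    support with integer arithmetic (no floating point, no tie tolerance
    needed)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted q-values from the step-up definition:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def nb_exact_p_enumeration(a_obs: int, b_obs: int, n1: int, n2: int, phi: float) -> float:
    """Exact NB test p-value by a plain Python loop over all splits of
    s = a + b, multiplying pmf values on the probability scale."""
    s = a_obs + b_obs
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    if phi < 1e-8:
        point = [float(binom.pmf(k, s, n1 / (n1 + n2))) for k in range(s + 1)]
    else:
        r1, r2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        point = [
            float(nbinom.pmf(k, r1, r1 / (r1 + m1)) * nbinom.pmf(s - k, r2, r2 / (r2 + m2)))
            for k in range(s + 1)
        ]
    p_obs = point[a_obs]
    total = sum(point)
    kept = sum(p for p in point if p <= p_obs * (1 + 1e-7))
    return min(kept / total, 1.0)


def binomial_minlik_p(a_obs: int, s: int) -> float:
    """Two-sided minimum-likelihood exact binomial(s, 1/2) test."""
    point = [float(binom.pmf(k, s, 0.5)) for k in range(s + 1)]
    p_obs = point[a_obs]
    return min(sum(p for p in point if p <= p_obs * (1 + 1e-7)), 1.0)


def noiseq_q_recount(x, cols1, cols2, k):
    """Double-loop recount of the nonparametric DE probability for every gene.

    x: genes x samples RPKM array; cols1/cols2: replicate column indices of
    the two conditions; k: pseudo-count.
    """
    G = x.shape[0]
    pool = []
    for cols in (cols1, cols2):
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                for g in range(G):
                    xa, xb = x[g, cols[i]], x[g, cols[j]]
                    pool.append((abs(np.log2((xa + k) / (xb + k))), abs(xa - xb)))
    q = np.zeros(G)
    for g in range(G):
        m1 = np.mean([x[g, c] for c in cols1])
        m2 = np.mean([x[g, c] for c in cols2])
        M = abs(np.log2((m1 + k) / (m2 + k)))
        D = abs(m1 - m2)
        hits = sum(1 for (pm, pd_) in pool if pm < M and pd_ < D)
        q[g] = hits / len(pool)
    return q
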