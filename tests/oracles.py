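"""Independent brute-force oracles used to cross-check the rank statistics.

Everything here is computed from first principles (explicit mid-ranks,
exhaustive enumeration, direct formula evaluation) without calling the
package's implementations or scipy's test functions.
"""

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np


def midranks(values):
    """Mid-ranks by counting: rank = #smaller + (#equal + 1) / 2."""
    values = np.asarray(values, float)
    out = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def _tie_term(values):
    _, counts = np.unique(np.asarray(values, float), return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis_oracle(groups):
    """Tie-corrected H from the rank-sum definition."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    h, pos = 0.0, 0
    for g in groups:
        r = ranks[pos: pos + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        pos += len(g)
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    return h / correction


def _normal_sf(z):
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def dunn_oracle(groups, pair, family_size):
    """(z, raw p, adjusted p) for one Dunn pair, by direct formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = midranks(pooled)
    means, pos = [], 0
    for g in groups:
        means.append(ranks[pos: pos + len(g)].mean())
        pos += len(g)
    i, j = pair
    ni, nj = len(groups[i - 1]), len(groups[j - 1])
    var = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    z = (means[i - 1] - means[j - 1]) / sqrt(var * (1.0 / ni + 1.0 / nj))
    p = 2.0 * _normal_sf(abs(z))
    return z, p, min(1.0, family_size * p)


def mann_whitney_enumeration(x, y):
    """(U_x, exact two-sided p) by enumerating all group labelings.

    Valid for tie-free pooled data; p = fraction of labelings whose U is at
    least as extreme (two-sided around n_x n_y / 2) as the observed one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    nx = len(x)
    ranks = midranks(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * len(y) / 2.0
    count = total = 0
    for labels in combinations(range(len(pooled)), nx):
        u = midranks(pooled)[list(labels)].sum() - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def mann_whitney_normal_approx(x, y):
    """Tie- and continuity-corrected normal approximation, by formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = midranks(np.concatenate([x, y]))
    u = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - _tie_term(np.concatenate([x, y]))
                            / (n * (n - 1)))
    z = max(abs(u - mu) - 0.5, 0.0) / sqrt(var)
    return u, min(1.0, 2.0 * _normal_sf(z))


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric table probabilities.

    Tables (at the observed margins) whose probability does not exceed the
    observed table's are accumulated, with the same relative tolerance scipy
    applies at the boundary.
    """
    (a, b), (c, d) = np.asarray(table, int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(0, c1 + 1)
               if prob(k) <= p_obs * (1.0 + 1e-7))
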