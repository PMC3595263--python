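"""Independent reference implementations used to cross-check the package.

These deliberately take different computational routes from the library:
textbook formulas evaluated directly, and an exhaustive UPGMA that recomputes
every inter-cluster average from the original leaf distances at each step
(the library uses the Lance-Williams update instead).
"""

import math

import numpy as np
from scipy import stats


def t_test_oracle(d):
    """Paired t from the textbook formula plus the Student t survival
    function; two-sided p with n-1 degrees of freedom."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def pearson_oracle(x, y):
    """Direct-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def sem_oracle(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = values.sum() / n
    sd = math.sqrt(((values - mean) ** 2).sum() / (n - 1))
    return mean, sd / math.sqrt(n)


def upgma_oracle(ids, dist):
    """Naive UPGMA: clusters are explicit leaf-index sets and every candidate
    inter-cluster distance is the average over all cross pairs of *leaf*
    distances, recomputed from the original matrix each step. Ties are broken
    by the lexicographically smallest member id. Returns the merge heights in
    merge order."""
    dist = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(len(ids))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
                d = sum(dist[i, j] for i, j in pairs) / len(pairs)
                key = tuple(sorted((
                    min(ids[i] for i in clusters[a]),
                    min(ids[j] for j in clusters[b]),
                )))
                if best is None or d < best[0] or (d == best[0] and key < best[1]):
                    best = (d, key, a, b)
        d, _, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights
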