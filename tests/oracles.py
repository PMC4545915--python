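"""Independent brute-force reference implementations used only by tests.

Each oracle restates its statistic from the definition (explicit loops,
exhaustive enumeration) so that agreement with the package is a two-route
check, not a tautology.
"""

import itertools
import math

import numpy as np
from scipy.stats import binom, hypergeom, rankdata
from scipy.stats import t as t_dist


def welch_oracle(a, b):
    """Welch t, Satterthwaite df and two-sided p from the closed formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1 = sum((x - a.mean()) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - b.mean()) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p_values):
    """BH step-up from the definition: q_i = min over j with p_(j) >= p_i of
    p_(j) * n / rank(j), capped at 1."""
    p = list(p_values)
    n = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        candidates = [
            ranked[j] * n / (j + 1) for j in range(n) if ranked[j] >= pi
        ]
        out.append(min(1.0, min(candidates)))
    return np.array(out)


def pearson_oracle(x, y):
    """Pearson r from the covariance/variance definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def ward_d2_oracle(distance_matrix):
    """Exhaustive Ward.D2 agglomeration.

    Recomputes every intercluster distance each step via the Lance-Williams
    update on squared dissimilarities; merge height is the (unsquared)
    distance at which the pair fuses. Returns a list of
    (frozenset_left, frozenset_right, height) merges.
    """
    D = np.asarray(distance_matrix, float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d2 = {frozenset([i, j]): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, j in itertools.combinations(keys, 2):
            val = d2[frozenset([i, j])]
            if best is None or val < best[0] - 1e-15:
                best = (val, i, j)
        val, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], math.sqrt(val)))
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in keys:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik = d2[frozenset([i, k])]
            djk = d2[frozenset([j, k])]
            dij = d2[frozenset([i, j])]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            d2[frozenset([next_id, k])] = new
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
    return merges


def ssgsea_oracle(values, ids, signature_genes, exponent):
    """Literal running-sum enumeration of the single-sample enrichment score."""
    G = len(values)
    member = [i in set(signature_genes) for i in ids]
    m = sum(member)
    ranks = rankdata(values)
    order = sorted(range(G), key=lambda i: (-values[i], ids[i]))
    total_w = sum(ranks[i] ** exponent for i in order if member[i])
    score = 0.0
    cum_sig = 0.0
    cum_bg = 0.0
    for i in order:
        if member[i]:
            cum_sig += ranks[i] ** exponent / total_w
        else:
            cum_bg += 1.0 / (G - m)
        score += cum_sig - cum_bg
    return score


def binomial_oracle(k, n, p0):
    """Exact two-sided binomial p by summing outcomes with probability <= P(k)."""
    probs = [binom.pmf(x, n, p0) for x in range(n + 1)]
    cutoff = probs[k] * (1 + 1e-9)
    return min(1.0, sum(p for p in probs if p <= cutoff))


def fisher_oracle(table):
    """Two-tailed Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d
    probs = []
    for x in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        probs.append((x, hypergeom.pmf(x, total, col1, row1)))
    observed = dict(probs)[a]
    return min(1.0, sum(p for _, p in probs if p <= observed * (1 + 1e-9)))
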