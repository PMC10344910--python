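"""Textbook-formula statistics oracle.

Each test statistic here is computed directly from its classical formula
(sums of squares, pooled variances, expected counts), using scipy only for
the reference distributions' CDFs.  Serves as the independent cross-check
for ``iolsvr.metrics``; intentionally not vectorized or optimized.
"""

import math

from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import studentized_range
from scipy.stats import t as t_dist


def anova_f(groups):
    k = len(groups)
    ns = [len(g) for g in groups]
    n = sum(ns)
    grand = sum(sum(g) for g in groups) / n
    means = [sum(g) / len(g) for g in groups]
    ss_between = sum(m * (mu - grand) ** 2 for m, mu in zip(ns, means))
    ss_within = sum(sum((x - mu) ** 2 for x in g) for g, mu in zip(groups, means))
    df1 = k - 1
    df2 = n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        return math.inf, df1, df2, 0.0
    F = (ss_between / df1) / (ss_within / df2)
    p = 1.0 - f_dist.cdf(F, df1, df2)
    return F, df1, df2, p


def welch_t(g1, g2):
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    v1 = sum((x - m1) ** 2 for x in g1) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in g2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * (1.0 - t_dist.cdf(abs(t), df))
    return t, df, p


def pearson_chi2_2x2(k1, n1, k2, n2):
    observed = [[k1, n1 - k1], [k2, n2 - k2]]
    row = [n1, n2]
    col = [k1 + k2, (n1 - k1) + (n2 - k2)]
    total = n1 + n2
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / total
            stat += (observed[i][j] - expected) ** 2 / expected
    p = 1.0 - chi2_dist.cdf(stat, 1)
    return stat, p


def variance_ratio_f(sd1, n1, sd2, n2):
    F = sd1 ** 2 / sd2 ** 2
    df1, df2 = n1 - 1, n2 - 1
    lower = f_dist.cdf(F, df1, df2)
    p = 2.0 * min(lower, 1.0 - lower)
    return F, df1, df2, min(p, 1.0)


def holm_stepdown(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = (m - rank) * pvals[idx]
        running = max(running, candidate)
        adjusted[idx] = min(1.0, running)
    return adjusted


def tukey_pairwise(groups):
    """All pairwise p-values via the studentized range distribution."""
    k = len(groups)
    ns = [len(g) for g in groups]
    means = [sum(g) / len(g) for g in groups]
    df = sum(ns) - k
    ss_within = sum(
        sum((x - mu) ** 2 for x in g) for g, mu in zip(groups, means)
    )
    mse = ss_within / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0.0:
                q = 0.0 if means[i] == means[j] else math.inf
            else:
                se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
            if q == 0.0:
                p = 1.0
            elif math.isinf(q):
                p = 0.0
            else:
                p = 1.0 - studentized_range.cdf(q, k, df)
            out[(i, j)] = (q, p)
    return out
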