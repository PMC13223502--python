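"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, dense grids, direct
textbook formulas) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def grid_rss_biexp(b, s, f_bounds, ds_bounds, df_bounds, n=50):
    """Minimum residual sum of squares over a dense (f, d_slow, d_fast) grid."""
    fs = np.linspace(f_bounds[0], f_bounds[1], n)
    dss = np.linspace(ds_bounds[0], ds_bounds[1], n)
    dfs = np.linspace(df_bounds[0], df_bounds[1], n)
    es = np.exp(-np.outer(dss, b))  # (n, nb)
    ef = np.exp(-np.outer(dfs, b))  # (n, nb)
    best = np.inf
    for f in fs:
        # model[i_ds, i_df, :] = f * ef[i_df] + (1 - f) * es[i_ds]
        model = f * ef[None, :, :] + (1.0 - f) * es[:, None, :]
        rss = ((model - s) ** 2).sum(axis=-1)
        best = min(best, float(rss.min()))
    return best


def mann_whitney_u(a, b):
    """First-sample-sided U by direct pair counting (ties count half)."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def mann_whitney_exact_p(a, b):
    """Exact two-sided permutation p for tie-free samples.

    Enumerates every assignment of the pooled values to the two groups and
    accumulates the probability of a U at least as far from its null mean
    as the observed one (the distribution is symmetric without ties).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = mann_whitney_u(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mann_whitney_u(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def _average_ranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H by the direct rank-sum formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    ranks = _average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = ranks[start:start + k].mean()
        h += k * rbar ** 2
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / correction


def spearman_rho(x, y):
    """Spearman rho: Pearson correlation of average ranks."""
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def pairwise_auc(pos, neg):
    """Empirical AUC by exhaustive pairwise comparison (ties count half)."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / pos.size / neg.size)


def chi_square_stat(table):
    """Pearson chi-square statistic by the definitional formula."""
    t = np.asarray(table, float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / t.sum()
    return float(((t - expected) ** 2 / expected).sum())
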