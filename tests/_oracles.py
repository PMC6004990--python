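"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — double loops, direct textbook
formulas, exhaustive enumeration — and shares no code path with the package.
"""
from __future__ import annotations

import math

import numpy as np


def pairwise_correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows of X, by an explicit double loop."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            r = (xi * xj).sum() / math.sqrt((xi**2).sum() * (xj**2).sum())
            D[i, j] = 1.0 - r
    np.fill_diagonal(D, 0.0)
    return D


def naive_upgma(D: np.ndarray):
    """O(n^3) UPGMA from a square distance matrix.

    Returns (merge_heights, merge_members): the height of each merge and the
    frozenset of leaf indices of the cluster it creates, in merge order.
    """
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights, members = [], []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(d)
        members.append(merged)
    return heights, members


def cophenetic_from_merges(n: int, heights, members) -> np.ndarray:
    """Cophenetic distances: height of the first merge joining each pair."""
    C = np.zeros((n, n))
    remaining = {(i, j) for i in range(n) for j in range(i + 1, n)}
    for h, mem in zip(heights, members):
        joined = {(i, j) for (i, j) in remaining if i in mem and j in mem}
        for i, j in joined:
            C[i, j] = C[j, i] = h
        remaining -= joined
    return C


def pearson(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def welch_t(a, b):
    """Welch two-sample t and two-sided p by the textbook formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n), by direct enumeration."""
    total = 0.0
    denom = math.comb(M, n)
    for j in range(k, min(K, n) + 1):
        if n - j <= M - K:
            total += math.comb(K, j) * math.comb(M - K, n - j) / denom
    return min(total, 1.0)


def anova_f(groups):
    """One-way fixed-effects ANOVA F and p from explicit sums of squares."""
    from scipy.stats import f as fdist

    groups = [np.asarray(g, float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    F = (ss_between / df_between) / (ss_within / df_within)
    return F, float(fdist.sf(F, df_between, df_within))


def chi_square_stat(observed: np.ndarray) -> float:
    """Sum (O - E)^2 / E with expected counts from the margins."""
    observed = np.asarray(observed, float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    return float(((observed - expected) ** 2 / expected).sum())


def mann_whitney_auc(scores_pos, scores_neg) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count half)."""
    total = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(scores_pos) * len(scores_neg))


def deviation_score_two_loop(matrix, labels, genes, subtype) -> float:
    """Eq.-style deviation score via explicit per-gene loops over samples."""
    total = 0.0
    for g in genes:
        in_sub = [matrix.at[g, s] for s in matrix.columns if labels[s] == subtype]
        everyone = [matrix.at[g, s] for s in matrix.columns]
        xbar = sum(in_sub) / len(in_sub)
        ybar = sum(everyone) / len(everyone)
        total += (xbar - ybar) ** 2
    return total / len(genes)
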