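"""Independent brute-force reference implementations used only by tests.

Deliberately naive (loops, enumeration, textbook formulas) and independent
of the package's code paths.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np


def median(values) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def mad(values) -> float:
    m = median(values)
    return median([abs(v - m) for v in values])


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vx * vy) ** 0.5


def rankdata(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    return pearson(rankdata(x), rankdata(y))


def mannwhitney_u(x, y) -> float:
    """U statistic for the first sample, counting ties as 1/2."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def wilcoxon_exact(diffs) -> tuple[float, float]:
    """(W+, two-sided exact p) by enumerating all 2^n sign assignments."""
    d = [v for v in diffs if v != 0.0]
    n = len(d)
    ranks = rankdata([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    total = len(ws)
    p_le = sum(w <= w_obs + 1e-12 for w in ws) / total
    p_ge = sum(w >= w_obs - 1e-12 for w in ws) / total
    return float(w_obs), min(1.0, 2.0 * min(p_le, p_ge))


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho (small n only)."""
    rho = abs(spearman_rho(x, y))
    count = 0
    total = 0
    for perm in permutations(y):
        total += 1
        if abs(spearman_rho(x, list(perm))) >= rho - 1e-12:
            count += 1
    return count / total


def group_medians(matrix: np.ndarray, columns) -> list[float]:
    """Per-row median over a column subset."""
    return [median([matrix[i, j] for j in columns]) for i in range(matrix.shape[0])]


def pairwise_correlations(X: np.ndarray) -> np.ndarray:
    """Double-loop Pearson matrix over rows of X."""
    m = X.shape[0]
    C = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            C[i, j] = C[j, i] = pearson(list(X[i]), list(X[j]))
    return C
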