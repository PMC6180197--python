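"""Independent oracles used by the test suite.

Everything here is deliberately naive (explicit loops, np.polyfit on raw
indices) and shares no code with the package, so agreement is evidence,
not tautology.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def naive_adaptive_trend(u: np.ndarray, w: int) -> np.ndarray:
    """Loop-based AFA trend: overlapping quadratic fits, linear blending."""
    u = np.asarray(u, dtype=float)
    big_n = u.size
    n = (w - 1) // 2
    starts = []
    s = 0
    while s + w <= big_n:
        starts.append(s)
        s += n
    if starts[-1] + w < big_n:
        starts.append(big_n - w)

    fits = {}
    for s0 in starts:
        x = np.arange(w, dtype=float)
        coef = np.polyfit(x, u[s0:s0 + w], 2)
        fits[s0] = np.polyval(coef, x)

    trend = np.empty(big_n)
    covered = 0
    for s0 in starts:
        fit = fits[s0]
        if s0 >= covered:
            trend[s0:s0 + w] = fit
        else:
            m = covered - s0
            for l in range(1, m + 1):
                w2 = (l - 1) / (m - 1) if m > 1 else 0.5
                trend[s0 + l - 1] = (1 - w2) * trend[s0 + l - 1] + w2 * fit[l - 1]
            trend[covered:s0 + w] = fit[m:]
        covered = s0 + w
    return trend


def naive_fluctuation(u: np.ndarray, w: int) -> float:
    u = np.asarray(u, dtype=float)
    v = naive_adaptive_trend(u, w)
    total = 0.0
    for i in range(u.size):
        total += (u[i] - v[i]) ** 2
    return float(np.sqrt(total / u.size))


def naive_profile(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    mean = u.mean()
    out = np.empty(u.size)
    acc = 0.0
    for i in range(u.size):
        acc += u[i] - mean
        out[i] = acc
    return out


def exact_wilcoxon_p(d: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Valid for tie-free |d| (symmetric null distribution)."""
    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    n = d.size
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    hits = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / 2 ** n


def exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided U-test p by enumerating all C(n1+n2, n1) group labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size

    def u_stat(idx_a: tuple) -> float:
        group_a = pooled[list(idx_a)]
        group_b = np.delete(pooled, list(idx_a))
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    mu = n1 * (pooled.size - n1) / 2.0
    u_obs = u_stat(tuple(range(n1)))
    hits = total = 0
    for idx in combinations(range(pooled.size), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def binomial_cascade(levels: int, p: float, seed: int) -> np.ndarray:
    """Multiplicative binomial cascade: a canonical multifractal measure."""
    rng = np.random.default_rng(seed)
    m = np.ones(1)
    for _ in range(levels):
        left = np.where(rng.random(m.size) < 0.5, p, 1.0 - p)
        m = np.column_stack([m * left, m * (1.0 - left)]).ravel()
    return m * m.size
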