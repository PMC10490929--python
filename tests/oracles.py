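"""Independent brute-force oracles for the statistical primitives.

Everything here is deliberately naive — O(n^2) pair counting, exhaustive
enumeration, explicit tail sums — and shares no code with the package, so
agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import norm


def brute_ranks(values) -> list[float]:
    """Average ranks by pairwise counting."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2)
    return out


def brute_spearman(x, y) -> float | None:
    """Pearson correlation of brute-force ranks via explicit sums."""
    rx, ry = brute_ranks(x), brute_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def bh_stepup(p_values) -> list[float]:
    """Benjamini-Hochberg by direct enumeration of p*m/rank with step-down
    (from the largest rank) monotone flattening."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p_values[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def mw_u(x, y) -> float:
    """U statistic for x by pair counting (ties count one half)."""
    return sum((a > b) + 0.5 * (a == b) for a in x for b in y)


def mw_exact_p(x, y) -> float:
    """Exact one-sided (x greater) Mann-Whitney p by enumerating every
    assignment of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    k, n = len(x), len(pooled)
    u_obs = mw_u(x, y)
    hits = total = 0
    for comb in itertools.combinations(range(n), k):
        in_x = set(comb)
        xs = [pooled[i] for i in range(n) if i in in_x]
        ys = [pooled[i] for i in range(n) if i not in in_x]
        total += 1
        hits += mw_u(xs, ys) >= u_obs - 1e-12
    return hits / total


def mw_normal_p(x, y) -> float:
    """Tie-corrected normal approximation with continuity correction for the
    one-sided (x greater) Mann-Whitney test."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    u = mw_u(x, y)
    mu = n1 * n2 / 2
    ties = {}
    for v in list(x) + list(y):
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values())
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u - mu - 0.5) / math.sqrt(sigma2)
    return float(norm.sf(z))


def fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p = hypergeometric upper tail, by explicit sums of
    binomial coefficients."""
    big_n = a + b + c + d
    row = a + b       # risk drugs
    col = a + c       # positively correlated drugs
    denom = math.comb(big_n, col)
    p = 0.0
    for i in range(a, min(row, col) + 1):
        if col - i <= big_n - row:
            p += math.comb(row, i) * math.comb(big_n - row, col - i) / denom
    return p


def auc_pairs(scores, labels) -> float | None:
    """AUC by enumerating every (positive, negative) pair; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return None
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
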