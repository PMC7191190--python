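"""Independent brute-force oracles used only by the tests.

These deliberately re-derive the statistics from first principles
(exact integer arithmetic, O(n^2) pair counting, naive rank formulas)
so they share no code with the implementation they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def exact_r_by_2_p(table) -> Fraction:
    """Two-sided exact p for an r x 2 table by full enumeration with
    exact rational arithmetic.

    Enumerates every table with the observed margins; the probability of
    a table is proportional to prod_i C(n_i, a_i) (first-column entries
    a_i, row sums n_i), and the p-value sums the probabilities of all
    tables no more probable than the observed one.
    """
    t = [list(map(int, row)) for row in table]
    t = [row for row in t if sum(row) > 0]
    if len(t) < 2:
        return Fraction(1)
    rows = [a + b for a, b in t]
    c1 = sum(a for a, _ in t)
    c2 = sum(b for _, b in t)
    if c1 == 0 or c2 == 0:
        return Fraction(1)
    w_obs = math.prod(math.comb(n, a) for n, (a, _) in zip(rows, t))
    total = 0
    tail = 0
    ranges = [range(0, n + 1) for n in rows]
    for combo in itertools.product(*ranges):
        if sum(combo) != c1:
            continue
        w = math.prod(math.comb(n, a) for n, a in zip(rows, combo))
        total += w
        if w <= w_obs:
            tail += w
    return Fraction(tail, total)


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau by O(n^2) concordant/discordant counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    # ties counted per pair: n1 = pairs tied in x, n2 = pairs tied in y
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return math.nan
    return (conc - disc) / denom


def _ranks_with_ties(values) -> np.ndarray:
    """Average ranks, computed naively."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def kruskal_h(groups) -> float:
    """Kruskal-Wallis H with tie correction, from the rank formula."""
    all_values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(all_values)
    ranks = _ranks_with_ties(all_values)
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        r = ranks[start : start + k]
        h += r.sum() ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_values, return_counts=True)
    tie = sum(c**3 - c for c in counts)
    correction = 1.0 - tie / (n**3 - n)
    return h / correction if correction > 0 else math.nan


def dunn_z_pairs(values, groups) -> dict:
    """Dunn pairwise z statistics from the joint-rank formula."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = _ranks_with_ties(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = sum(c**3 - c for c in counts)
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    levels = sorted(set(groups.tolist()))
    out = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            ra = ranks[groups == a]
            rb = ranks[groups == b]
            se = math.sqrt(var_factor * (1.0 / len(ra) + 1.0 / len(rb)))
            out[(a, b)] = (ra.mean() - rb.mean()) / se
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, naive implementation."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * n / rank_from_top)
        adjusted[idx] = val
        prev = val
    return adjusted
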