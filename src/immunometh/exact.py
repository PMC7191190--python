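"""Exact test of homogeneity for r x 2 contingency tables.

For a table with r rows (groups) and two columns (e.g. methylated /
unmethylated counts per reference cell type), the null distribution
conditions on both margins.  With two columns the table is determined by
its first-column vector ``a`` and, for fixed margins,

    P(a) = prod_i C(n_i, a_i) / C(N, c1)

where ``n_i`` are the row totals, ``N`` the grand total and ``c1`` the
first-column total.  The two-sided p-value is the total probability of
all tables at most as probable as the observed one (the Freeman-Halton
extension of Fisher's exact test, specialised to two columns).

Tables are enumerated exactly whenever the number of tables in the
conditional reference set (computed by dynamic programming) is small
enough; beyond that a seeded Monte-Carlo estimate over margin-preserving
random tables is returned instead, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import random_table

__all__ = ["ExactTestResult", "fisher_exact_r_by_2", "count_tables"]

# relative slack (in log space) when comparing table probabilities, so a
# table whose probability equals the observed one up to float rounding is
# still counted in the tail
_LOG_TOL = 1e-9


@dataclass(frozen=True)
class ExactTestResult:
    p: float
    method: str  # "enumeration" | "monte-carlo" | "degenerate"
    n_tables: int | None = None
    n_draws: int | None = None


def _log_binom(n: int, k: np.ndarray | int) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def count_tables(row_sums: np.ndarray, c1: int) -> int:
    """Number of r x 2 tables with the given row sums and first-column sum."""
    counts = np.zeros(c1 + 1, dtype=np.float64)
    counts[0] = 1.0
    for n_i in row_sums:
        new = np.zeros_like(counts)
        for a in range(min(int(n_i), c1) + 1):
            new[a:] += counts[: c1 + 1 - a]
        counts = new
    return int(round(counts[c1]))


def _enumerate_tail(row_sums: np.ndarray, c1: int, lw_obs: float) -> tuple[float, int]:
    """Exact tail probability by vectorised enumeration over first columns.

    Returns (p, number of tables enumerated).
    """
    suffix = np.concatenate([np.cumsum(row_sums[::-1])[::-1], [0]])
    states: dict[int, np.ndarray] = {0: np.zeros(1)}
    for idx, n_i in enumerate(row_sums):
        lb = _log_binom(int(n_i), np.arange(int(n_i) + 1))
        new: dict[int, list[np.ndarray]] = {}
        remaining = suffix[idx + 1]
        for s, arr in states.items():
            for a in range(int(n_i) + 1):
                t = s + a
                if t > c1:
                    break
                if t + remaining < c1:  # cannot reach c1 any more
                    continue
                new.setdefault(t, []).append(arr + lb[a])
        states = {t: np.concatenate(v) for t, v in new.items()}
    lw = states[c1]
    log_z = _log_binom(int(np.sum(row_sums)), c1)
    mask = lw <= lw_obs + _LOG_TOL
    p = float(np.exp(logsumexp(lw[mask]) - log_z))
    return min(p, 1.0), lw.size


def fisher_exact_r_by_2(
    table,
    max_tables: int = 200_000,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> ExactTestResult:
    """Two-sided exact test for an r x 2 table of counts.

    Parameters
    ----------
    table
        (r, 2) array of non-negative integer counts.
    max_tables
        Enumerate exactly when the conditional reference set holds at most
        this many tables, otherwise fall back to Monte-Carlo.
    mc_draws, seed
        Monte-Carlo sample size and RNG seed for the fallback.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError(f"expected an r x 2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[t.sum(axis=1) > 0]  # empty rows carry no information
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if t.shape[0] < 2 or (col_sums == 0).any():
        return ExactTestResult(p=1.0, method="degenerate")

    c1 = int(col_sums[0])
    lw_obs = float(np.sum(_log_binom(row_sums, t[:, 0])))
    n_tab = count_tables(row_sums, c1)
    if n_tab <= max_tables:
        p, n_enum = _enumerate_tail(row_sums, c1, lw_obs)
        return ExactTestResult(p=p, method="enumeration", n_tables=n_enum)

    rng = np.random.default_rng(seed)
    dist = random_table(row_sums, col_sums)
    draws = dist.rvs(mc_draws, random_state=rng, method="patefield")
    # for fixed margins P(T) is proportional to 1 / prod a_ij!
    lw = -gammaln(draws + 1.0).sum(axis=(1, 2))
    lw_o = -float(gammaln(t + 1.0).sum())
    hits = int(np.count_nonzero(lw <= lw_o + _LOG_TOL))
    p = (1.0 + hits) / (1.0 + mc_draws)
    return ExactTestResult(p=min(p, 1.0), method="monte-carlo", n_draws=mc_draws)
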