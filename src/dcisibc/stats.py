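"""Shared statistical engines: rank tests, exact contingency tests, FDR.

Every hypothesis test in the pipeline (differential methylation, the
subtype-stratified group comparisons, the subtype/ER distribution tests)
routes through this module so that test conventions — two-sidedness, tie
handling, exact-vs-approximate switching — are decided in exactly one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MannWhitneyResult",
    "mann_whitney_u",
    "bh_fdr",
    "fisher_exact_table",
    "spearman",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    n_x: int
    n_y: int


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and the data contain no ties; otherwise the normal approximation
    with continuity and tie correction. The U statistic reported is for the
    first sample (number of (x, y) pairs with x > y, ties counted half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty groups")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_x=int(x.size),
        n_y=int(y.size),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _table_log_prob(table: np.ndarray, lgamma_cache=math.lgamma) -> float:
    """Log probability of a 2xK table under fixed margins (multivariate
    hypergeometric)."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(lgamma_cache(r + 1) for r in row)
        + sum(lgamma_cache(c + 1) for c in col)
        - lgamma_cache(n + 1)
        - sum(lgamma_cache(v + 1) for v in table.ravel())
    )
    return lp


def _freeman_halton_2xk(table: np.ndarray) -> float:
    """Exact two-sided p for a 2xK table: sum of probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's (with a small relative tolerance for float comparison)."""
    col = table.sum(axis=0)
    r0 = int(table.sum(axis=1)[0])
    obs_lp = _table_log_prob(table)
    tol = 1e-7
    p_total = 0.0
    ranges = [range(int(c) + 1) for c in col]
    for top in product(*ranges):
        if sum(top) != r0:
            continue
        cand = np.array([list(top), [int(c) - t for c, t in zip(col, top)]])
        lp = _table_log_prob(cand)
        if lp <= obs_lp + tol:
            p_total += math.exp(lp)
    return min(p_total, 1.0)


def _monte_carlo_2xk(table: np.ndarray, n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    col = table.sum(axis=0)
    r0 = int(table.sum(axis=1)[0])
    obs_lp = _table_log_prob(table)
    tol = 1e-7
    # Draw row-0 counts from the multivariate hypergeometric given margins.
    draws = rng.multivariate_hypergeometric(col.astype(int), r0, size=n_perm)
    hits = 0
    for top in draws:
        cand = np.vstack([top, col - top])
        if _table_log_prob(cand) <= obs_lp + tol:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def fisher_exact_table(
    table, *, max_exact_n: int = 200, n_perm: int = 100_000, seed: int = 0
) -> tuple[float, str]:
    """Two-sided Fisher-type exact test on a 2xK contingency table.

    2x2 tables use the classical two-sided Fisher exact test (sum of
    hypergeometric probabilities <= the observed table's). Wider tables use
    the Freeman-Halton generalisation, enumerated exactly when the total
    count is <= ``max_exact_n`` and otherwise estimated by Monte-Carlo
    sampling of tables with the observed margins (fixed seed).

    Returns ``(p_value, method)`` with method in {"fisher-2x2",
    "freeman-halton", "monte-carlo"}.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2xK with K >= 2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty margin")
    if t.shape[1] == 2:
        return float(sps.fisher_exact(t, alternative="two-sided")[1]), "fisher-2x2"
    if t.sum() <= max_exact_n:
        return _freeman_halton_2xk(t), "freeman-halton"
    return _monte_carlo_2xk(t, n_perm, seed), "monte-carlo"


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires >= 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("spearman undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
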