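"""Rank-based test statistics used across the pipeline.

The Mann-Whitney U test is the workhorse comparison for spot-level
quantities (expression, cell-type abundance, signature scores).  It is
implemented here natively so that small-sample p-values come from full
enumeration of group assignments -- exact even under ties -- while large
samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# Beyond this per-group size, enumeration of C(n1+n2, n1) assignments is
# replaced by the normal approximation (C(14,7) = 3432 is instant).
EXACT_MAX_N = 7


def _u_statistic(ranks: np.ndarray, idx: np.ndarray, n1: int) -> float:
    return float(ranks[idx].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y, exact: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Parameters
    ----------
    x, y
        The two samples.
    exact
        ``"auto"`` (enumerate when both groups have <= 7 observations),
        ``"always"`` or ``"never"``.

    Returns
    -------
    (U, p)
        U is the statistic for the first sample (midrank convention);
        p is the two-sided p-value.  The exact p enumerates every
        assignment of pooled values to groups and is valid under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, np.arange(n1), n1)

    use_exact = exact == "always" or (exact == "auto" and max(n1, n2) <= EXACT_MAX_N)
    if use_exact:
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, np.array(idx), n1)
            # tiny epsilon guards float round-off in midrank sums
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total
    return u_obs, _normal_p(u_obs, n1, n2, pooled)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def _normal_p(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:  # all values tied
        return 1.0
    # continuity correction toward the mean
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def rank_sum_matrix(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann-Whitney U of ``X[mask]`` vs ``X[~mask]``.

    Uses the tie-corrected normal approximation when either group exceeds
    the exact regime (the usual case for spot-level data), and full
    enumeration per column otherwise.  Returns (U, p) arrays of length
    ``X.shape[1]``.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if max(n1, n2) <= EXACT_MAX_N:
        pairs = [mann_whitney_u(X[mask, j], X[~mask, j]) for j in range(X.shape[1])]
        u = np.array([a for a, _ in pairs])
        p = np.array([b for _, b in pairs])
        return u, p
    n = n1 + n2
    ranks = sps.rankdata(X, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = np.array([_tie_term(X[:, j]) for j in range(X.shape[1])])
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.sqrt(var)
    z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * sps.norm.sf(z)), 1.0)
    return u, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
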