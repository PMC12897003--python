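"""Per-gene Mann-Whitney differential expression with Bonferroni control.

``mw_test`` uses the exact small-sample null distribution of the
rank-sum statistic (computed by dynamic programming) whenever the
combined sample is small (n_a + n_b <= 16) and tie-free, and otherwise
the normal approximation with tie and continuity corrections.  The
Bonferroni denominator is the number of genes actually tested: genes
with zero counts in both groups are skipped and excluded from it.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["mw_test", "run_deg", "overlap_deg", "EXACT_MAX_N"]

EXACT_MAX_N = 16  # exact enumeration up to this combined sample size


@lru_cache(maxsize=None)
def _u_null_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value for sizes (n, m).

    Dynamic program over the N = n + m ranks: state (ranks considered,
    chosen for group A, rank sum).  Returns counts indexed by
    U = ranksum - n(n+1)/2, length n*m + 1.
    """
    N = n + m
    max_sum = sum(range(N - n + 1, N + 1))
    # dp[k][s] = ways to choose k ranks among those seen with sum s
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r else dp[k - 1, :]
    offset = n * (n + 1) // 2
    counts = dp[n, offset: offset + n * m + 1]
    return tuple(int(c) for c in counts)


def _exact_p(u: float, n: int, m: int) -> float:
    """Two-sided symmetric-tail p: P(|U - nm/2| >= |u - nm/2|)."""
    counts = np.array(_u_null_counts(n, m), dtype=float)
    total = counts.sum()
    nm = n * m
    u_low = min(u, nm - u)
    lo = int(np.floor(u_low + 1e-9))
    p = (counts[: lo + 1].sum() + counts[int(np.ceil(nm - u_low - 1e-9)):].sum()) / total
    return float(min(1.0, p))


def mw_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p.

    Exact null enumeration when n_a + n_b <= 16 with no ties; normal
    approximation with tie and continuity corrections otherwise.  When
    every value in both groups is identical, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    ranks = rankdata(pooled)
    u = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        return u, _exact_p(u, a.size, b.size)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return u, float(res.pvalue)


def _vectorized_asymptotic(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise asymptotic MW over genes; zero-variance rows get p = 1."""
    na, nb = A.shape[1], B.shape[1]
    U = np.empty(A.shape[0])
    p = np.ones(A.shape[0])
    pooled = np.concatenate([A, B], axis=1)
    constant = np.all(pooled == pooled[:, :1], axis=1)
    var_rows = ~constant
    U[constant] = na * nb / 2.0
    if var_rows.any():
        res = mannwhitneyu(
            A[var_rows], B[var_rows], alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=1,
        )
        U[var_rows] = res.statistic
        p[var_rows] = res.pvalue
    return U, p


def run_deg(
    norm: pd.DataFrame,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Gene-wise Mann-Whitney DE between two cell groups.

    Genes with zero expression in both groups are skipped and excluded
    from the Bonferroni denominator.  Direction is "up" when mean
    normalized expression is higher in group A.  The log fold-change
    column is the difference of group mean log-normalized expression.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na < min_cells or nb < min_cells:
        raise ValueError(f"groups too small: {na} vs {nb} (min_cells={min_cells})")
    if np.any(mask_a & mask_b):
        raise ValueError("groups overlap")
    X = norm.to_numpy()
    A, B = X[:, mask_a], X[:, mask_b]
    expressed = (A.sum(axis=1) > 0) | (B.sum(axis=1) > 0)
    genes = np.asarray(norm.index)[expressed]
    A, B = A[expressed], B[expressed]
    n_tested = len(genes)
    if n_tested == 0:
        return pd.DataFrame(
            columns=["gene", "U", "p", "p_adj", "significant", "direction",
                     "mean_a", "mean_b", "lfc", "detect_frac_a", "detect_frac_b"]
        )
    if na + nb <= EXACT_MAX_N:
        stats = [mw_test(A[i], B[i]) for i in range(n_tested)]
        U = np.array([s[0] for s in stats])
        p = np.array([s[1] for s in stats])
    else:
        U, p = _vectorized_asymptotic(A, B)
    p_adj = np.minimum(1.0, p * n_tested)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": genes,
            "U": U,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= alpha,
            "direction": np.where(mean_a >= mean_b, "up", "down"),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "lfc": mean_a - mean_b,
            "detect_frac_a": (A > 0).mean(axis=1),
            "detect_frac_b": (B > 0).mean(axis=1),
        }
    ).reset_index(drop=True)


def overlap_deg(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    require_direction: bool = True,
) -> pd.DataFrame:
    """Genes significant in both tables, optionally direction-consistent.

    Records both adjusted p's and directions; the returned frame also
    carries up/down counts in ``df.attrs`` for reporting.
    """
    disc = discovery[discovery["significant"]][["gene", "direction", "p_adj"]]
    val = validation[validation["significant"]][["gene", "direction", "p_adj"]]
    merged = disc.merge(val, on="gene", suffixes=("_discovery", "_validation"))
    merged["direction_consistent"] = (
        merged["direction_discovery"] == merged["direction_validation"]
    )
    if require_direction:
        merged = merged[merged["direction_consistent"]]
    merged = merged.sort_values("gene").reset_index(drop=True)
    merged.attrs["n_overlap"] = len(merged)
    merged.attrs["n_up"] = int((merged["direction_discovery"] == "up").sum())
    merged.attrs["n_down"] = int((merged["direction_discovery"] == "down").sum())
    return merged
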