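"""Nonparametric statistics for paired segmentation comparisons.

Friedman omnibus test across methods (blocks = cases), post hoc Wilcoxon
signed-rank tests with Bonferroni adjustment, and the box-plot summary
convention (quartiles, 1.5*IQR whiskers, outlier flags) used for
reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["friedman_test", "wilcoxon_bonferroni", "box_stats", "BoxStats"]


def _rank_matrix(data: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, data)


def _friedman_statistic(data: np.ndarray) -> float:
    """Rank-based Friedman chi-square with the average-rank tie correction."""
    n, k = data.shape
    ranks = _rank_matrix(data)
    rbar = ranks.mean(axis=0)
    ss = n * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    correction = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        correction += np.sum(counts**3 - counts)
    denom = 1.0 - correction / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0  # all values tied in every block
    return float(12.0 / (k * (k + 1)) * ss / denom)


def friedman_test(data, method: str = "chisq") -> tuple[float, float]:
    """Friedman test on a complete blocks x treatments matrix.

    Parameters
    ----------
    data : array-like, shape (n_blocks, k_treatments)
        No missing cells; n >= 2 blocks, k >= 2 treatments.
    method : {'chisq', 'exact'}
        'chisq' (default, matching R's ``friedman.test``) refers the
        tie-corrected statistic to chi-square with k-1 df; 'exact'
        enumerates all within-block orderings (feasible for small n, k).

    Returns
    -------
    (statistic, p_value)
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 treatments")
    if not np.all(np.isfinite(data)):
        raise ValueError("matrix has missing cells")
    n, k = data.shape
    stat = _friedman_statistic(data)

    if method == "chisq":
        if stat == 0.0:
            return 0.0, 1.0
        return stat, float(sps.chi2.sf(stat, k - 1))
    if method == "exact":
        if math.factorial(k) ** n > 2_000_000:
            raise ValueError("exact enumeration infeasible for this size")
        perms = list(permutations(range(k)))
        count = 0
        total = 0
        for assignment in product(perms, repeat=n):
            permuted = np.array([data[i, list(assignment[i])] for i in range(n)])
            total += 1
            if _friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        return stat, count / total
    raise ValueError("method must be 'chisq' or 'exact'")


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Enumerate the signed-rank null (average ranks for tied |d|)."""
    r = sps.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    sums = np.zeros(1)
    for ri in r:  # distribution of W+ over all 2^n sign patterns
        sums = np.concatenate([sums, sums + ri])
    cdf = np.mean(sums <= w_obs + 1e-9)
    sf = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


def _wilcoxon_raw(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided signed-rank p: Pratt handling of zeros; exact enumeration
    for small zero-free samples, normal approximation otherwise."""
    d = x - y
    if np.all(d == 0):
        return 1.0
    if np.all(d != 0) and d.size <= 15:
        return float(_exact_signed_rank_p(d))
    res = sps.wilcoxon(x, y, zero_method="pratt", method="approx")
    return float(res.pvalue)


def wilcoxon_bonferroni(data, treatments=None, alpha: float = 0.05) -> pd.DataFrame:
    """Post hoc pairwise Wilcoxon signed-rank tests, Bonferroni adjusted.

    ``data`` is a blocks x treatments matrix.  The adjusted p-value is the
    raw p multiplied by the number of pairs, capped at 1; pairs are flagged
    significant against ``alpha``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 treatments")
    k = data.shape[1]
    if treatments is None:
        treatments = [f"T{j}" for j in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        p_raw = _wilcoxon_raw(data[:, i], data[:, j])
        p_adj = min(1.0, m * p_raw)
        rows.append({
            "pair": f"{treatments[i]} vs {treatments[j]}",
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


@dataclass
class BoxStats:
    """Five-number box-plot summary with 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray  # boolean flags aligned with the input sample


def box_stats(values) -> BoxStats:
    """Quartiles (linear interpolation between order statistics) + whiskers.

    Whiskers sit at Q1 - 1.5*IQR and Q3 + 1.5*IQR; values outside are
    flagged as outliers (removed from plots, not from analysis).
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)] if np.isnan(vals).any() else vals
    if vals.size == 0:
        raise ValueError("need at least one finite value")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return BoxStats(float(med), float(q1), float(q3), float(lo), float(hi),
                    (vals < lo) | (vals > hi))
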