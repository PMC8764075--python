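"""Shared statistical machinery: rank-sum test, one-way ANOVA with BH
correction, and quantile normalisation across libraries."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "anova_bh",
    "bh_adjust",
    "quantile_normalize",
]

_EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y, two_sided: bool = True) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    For combined sample sizes up to 12 the p-value is exact, from full
    enumeration of all assignments of the pooled (mid)ranks to the first
    sample, which remains valid under ties. Larger samples use the normal
    approximation with tie correction and continuity correction.

    Returns (W, p) where W is the rank-sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    m = x.size
    w_obs = ranks[:m].sum()
    if np.all(pooled == pooled[0]):
        return float(w_obs), 1.0
    if pooled.size <= _EXACT_MAX_N:
        n_le = n_ge = total = 0
        for idx in combinations(range(pooled.size), m):
            w = ranks[list(idx)].sum()
            total += 1
            if w <= w_obs + 1e-9:
                n_le += 1
            if w >= w_obs - 1e-9:
                n_ge += 1
        one_sided = min(n_le, n_ge) / total
        p = min(1.0, 2 * one_sided) if two_sided else one_sided
        return float(w_obs), float(p)
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided" if two_sided else "less",
        method="asymptotic", use_continuity=True,
    )
    return float(w_obs), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def anova_bh(groups_per_feature: list[list[np.ndarray]]) -> pd.DataFrame:
    """One-way ANOVA per feature followed by BH correction across features.

    ``groups_per_feature[f]`` is the list of per-group value arrays for
    feature f (one group per stage, replicates within). Features with zero
    total variance get NaN p and are flagged ``degenerate``.
    """
    n = len(groups_per_feature)
    F = np.full(n, np.nan)
    p = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)
    for i, groups in enumerate(groups_per_feature):
        arrs = [np.asarray(g, dtype=float) for g in groups]
        if len(arrs) < 2 or any(a.size < 2 for a in arrs):
            degenerate[i] = True
            continue
        allv = np.concatenate(arrs)
        if np.ptp(allv) == 0:
            degenerate[i] = True
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.f_oneway(*arrs)
        F[i], p[i] = res.statistic, res.pvalue
        if not np.isfinite(p[i]):
            # zero within-group variance: the F statistic is infinite but the
            # group effect is unambiguous
            if all(np.ptp(a) == 0 for a in arrs):
                p[i] = 0.0
            else:
                degenerate[i] = True
                p[i] = np.nan
    return pd.DataFrame({"F": F, "p": p, "fdr": bh_adjust(p), "degenerate": degenerate})


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns (libraries) to the mean-of-sorted reference.

    Every column is mapped onto the across-column mean of sorted values; tied
    values receive the average of the reference values their ranks span.
    """
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = sps.rankdata(X[:, j])  # average ranks for ties
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=table.index, columns=table.columns)
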