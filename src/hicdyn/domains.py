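"""TAD-level statistics: insulation scores, boundary calling and strength,
the intra-TAD connectivity (domain) score with its randomised-TAD null,
cross-stage variability selection, and stage-trend utilities.

The insulation score of a bin is the mean z-score of the contacts crossing it
between the ``window_bins`` bins on its left and the ``window_bins`` bins on
its right, where z-scores are taken per genomic-separation stratum over the
whole chromosome. Boundary strength is minus the insulation score.

The domain score of a TAD is the fraction of its associated cis contact pairs
that are fully intra-TAD. Scores are normalised in three steps: divide by the
mean score of randomly placed same-size TADs on the same chromosome, centre
by the library mean over all TADs, then quantile-normalise across libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.signal import find_peaks

from .contacts import ContactMatrix
from .stats import anova_bh, quantile_normalize

__all__ = [
    "InsulationProfile",
    "insulation_profile",
    "call_boundaries",
    "top_variable_boundaries",
    "domain_score_raw",
    "normalize_domain_scores",
    "variable_tads",
    "cluster_stage_series",
    "adjacent_stage_lfc",
]


@dataclass
class InsulationProfile:
    chrom: str
    bin_size: int
    window_bins: int
    score: np.ndarray  # mean z-score units; NaN at chromosome edges

    @property
    def boundary_strength(self) -> np.ndarray:
        return -self.score


def _zscore_by_distance(values: np.ndarray) -> np.ndarray:
    """Z-score each diagonal (separation stratum) of a symmetric matrix.

    Strata with zero spread map to all-zero z-scores.
    """
    n = values.shape[0]
    z = np.zeros_like(values, dtype=float)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        mu = diag.mean()
        sd = diag.std()
        zd = (diag - mu) / sd if sd > 0 else np.zeros_like(diag)
        idx = np.arange(n - d)
        z[idx, idx + d] = zd
        z[idx + d, idx] = zd
    return z


def insulation_profile(
    matrix: ContactMatrix, window_bins: int = 5, use: str = "raw"
) -> InsulationProfile:
    """Per-bin insulation score: mean z of the left x right crossing block."""
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = matrix.n_bins
    score = np.full(n, np.nan)
    if n < 2 * window_bins + 1:
        return InsulationProfile(matrix.chrom, matrix.bin_size, window_bins, score)
    z = _zscore_by_distance(matrix.values(use))
    w = window_bins
    for b in range(w, n - w):
        block = z[b - w:b, b + 1:b + 1 + w]
        score[b] = block.mean()
    return InsulationProfile(matrix.chrom, matrix.bin_size, window_bins, score)


def call_boundaries(
    profile: InsulationProfile,
    min_prominence: float = 0.1,
    min_strength_quantile: float = 0.0,
) -> pd.DataFrame:
    """TAD boundaries at prominent local minima of the insulation score.

    Candidates are local maxima of boundary strength with at least
    ``min_prominence`` prominence; a candidate is kept if its strength is at
    least the ``min_strength_quantile`` quantile of all finite strengths.
    Returns a table (bin, start, end, strength) sorted by coordinate.
    """
    strength = profile.boundary_strength
    filled = np.where(np.isfinite(strength), strength, -np.inf)
    peaks, _ = find_peaks(filled, prominence=min_prominence)
    if peaks.size and min_strength_quantile > 0:
        finite = strength[np.isfinite(strength)]
        if finite.size:
            cut = np.quantile(finite, min_strength_quantile)
            peaks = peaks[strength[peaks] >= cut]
    bs = profile.bin_size
    return pd.DataFrame({
        "bin": peaks.astype(int),
        "start": peaks.astype(int) * bs,
        "end": (peaks.astype(int) + 1) * bs,
        "strength": strength[peaks],
    })


def _merge_adjacent_bins(bins: np.ndarray, strengths: np.ndarray) -> np.ndarray:
    """Collapse runs of adjacent bins to the strongest bin of each run."""
    if bins.size == 0:
        return bins
    order = np.argsort(bins)
    bins, strengths = bins[order], strengths[order]
    out = []
    run = [0]
    for i in range(1, bins.size):
        if bins[i] - bins[run[-1]] <= 1:
            run.append(i)
        else:
            out.append(run[int(np.argmax(strengths[run]))])
            run = [i]
    out.append(run[int(np.argmax(strengths[run]))])
    return bins[out]


def top_variable_boundaries(
    profiles: dict[str, InsulationProfile],
    boundaries_per_stage: dict[str, pd.DataFrame],
    k: int = 1000,
) -> pd.DataFrame:
    """Rank the union of per-stage boundaries by cross-stage strength SD.

    Boundary strengths at each union bin are read from every stage's
    insulation profile; adjacent union bins are merged. Ties and the all-zero
    SD case break by ascending genomic coordinate. If fewer than ``k``
    boundaries exist, all are returned.
    """
    stages = list(profiles)
    allbins = np.concatenate([boundaries_per_stage[s]["bin"].to_numpy() for s in stages]) \
        if stages else np.array([], dtype=int)
    if allbins.size == 0:
        return pd.DataFrame(columns=["bin", "sd"] + stages)
    mean_strength = np.mean([profiles[s].boundary_strength for s in stages], axis=0)
    ubins = _merge_adjacent_bins(np.unique(allbins), mean_strength[np.unique(allbins)])
    per_stage = {s: profiles[s].boundary_strength[ubins] for s in stages}
    mat = np.vstack([per_stage[s] for s in stages])
    sd = np.nanstd(mat, axis=0, ddof=1)
    out = pd.DataFrame({"bin": ubins, "sd": sd})
    for s in stages:
        out[s] = per_stage[s]
    out = out.sort_values(["sd", "bin"], ascending=[False, True], kind="mergesort")
    return out.head(min(k, len(out))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Domain scores
# ---------------------------------------------------------------------------

class _TadScorer:
    """O(1) intra-TAD / at-least-one-end pair sums via 2D prefix sums."""

    def __init__(self, counts: np.ndarray):
        self._ps = np.zeros((counts.shape[0] + 1, counts.shape[1] + 1))
        self._ps[1:, 1:] = counts.cumsum(axis=0).cumsum(axis=1)
        diag = np.diagonal(counts)
        self._diag_cum = np.concatenate([[0.0], np.cumsum(diag)])
        rows = counts.sum(axis=1)
        self._row_cum = np.concatenate([[0.0], np.cumsum(rows)])
        self.n = counts.shape[0]

    def _block(self, s: int, e: int) -> float:
        ps = self._ps
        return ps[e, e] - ps[s, e] - ps[e, s] + ps[s, s]

    def score(self, s: int, e: int) -> float:
        """Domain score of TAD over bins [s, e): intra / (>=1 end in TAD)."""
        if not (0 <= s < e <= self.n):
            raise ValueError("TAD outside chromosome")
        block = self._block(s, e)          # ordered pairs both-in
        diag = self._diag_cum[e] - self._diag_cum[s]
        intra = (block + diag) / 2.0       # unordered pairs, diagonal once
        rowsum = self._row_cum[e] - self._row_cum[s]
        at_least_one = rowsum - (block - diag) / 2.0
        if at_least_one == 0:
            return np.nan
        return intra / at_least_one


def domain_score_raw(matrix: ContactMatrix, start_bin: int, end_bin: int) -> float:
    """Intra-TAD contact fraction: pairs with both ends in the TAD over pairs
    with at least one end in the TAD (cis only). 0/0 gives NaN."""
    return _TadScorer(matrix.counts).score(start_bin, end_bin)


def normalize_domain_scores(
    raw_scores: pd.DataFrame,
    matrices: dict[str, ContactMatrix],
    tads: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalise per-library domain scores against a randomised-TAD null.

    For each TAD and library: divide the raw score by the mean score of
    ``n_sim`` random placements of a same-size TAD on the same chromosome
    (uniform over valid start bins, with replacement), subtract the library
    mean over all TADs, then quantile-normalise the libraries against the
    mean-of-sorted reference.

    ``raw_scores``: TAD x library table of raw scores; ``tads`` must carry
    ``start_bin``/``end_bin`` aligned with its rows.
    """
    rng = np.random.default_rng(seed)
    libs = list(raw_scores.columns)
    scorers = {lib: _TadScorer(matrices[lib].counts) for lib in libs}
    n_bins = {lib: scorers[lib].n for lib in libs}
    ratio = pd.DataFrame(index=raw_scores.index, columns=libs, dtype=float)
    for idx, tad in tads.iterrows():
        size = int(tad["end_bin"] - tad["start_bin"])
        # one placement draw shared across libraries keeps libraries comparable
        max_start = min(n_bins[lib] for lib in libs) - size
        if max_start < 0:
            raise ValueError("chromosome shorter than TAD; cannot place null TADs")
        starts = rng.integers(0, max_start + 1, size=n_sim)
        for lib in libs:
            null = np.array([scorers[lib].score(s, s + size) for s in starts])
            mu = np.nanmean(null)
            ratio.loc[idx, lib] = raw_scores.loc[idx, lib] / mu if mu > 0 else np.nan
    centered = ratio - ratio.mean(axis=0)
    if len(libs) > 1:
        return quantile_normalize(centered)
    return centered


def variable_tads(
    scores: pd.DataFrame,
    stage_of_column: dict[str, str],
    fdr_cutoff: float = 0.001,
    k: int = 1000,
) -> pd.DataFrame:
    """Select the top-k most variable TADs among those significant by ANOVA.

    ``scores`` is a TAD x library table; ``stage_of_column`` maps each library
    column to its stage (replicates share a stage). A one-way ANOVA across
    stages with BH correction keeps TADs with FDR < ``fdr_cutoff``; survivors
    are ranked by the variance of their stage means (descending), ties broken
    by row order (genomic coordinate), and the top ``k`` returned.
    """
    stages = sorted(set(stage_of_column.values()), key=list(stage_of_column.values()).index)
    groups = []
    for _, row in scores.iterrows():
        groups.append([
            row[[c for c, s in stage_of_column.items() if s == st]].to_numpy(dtype=float)
            for st in stages
        ])
    res = anova_bh(groups)
    res.index = scores.index
    stage_means = pd.DataFrame({
        st: scores[[c for c, s in stage_of_column.items() if s == st]].mean(axis=1)
        for st in stages
    })
    res["stage_variance"] = stage_means.var(axis=1, ddof=1)
    keep = res[(res["fdr"] < fdr_cutoff) & ~res["degenerate"]]
    keep = keep.assign(_ord=np.arange(len(keep)))
    keep = keep.sort_values(["stage_variance", "_ord"], ascending=[False, True],
                            kind="mergesort").drop(columns="_ord")
    return keep.head(min(k, len(keep)))


def cluster_stage_series(
    feature_matrix: np.ndarray, n_clusters: int, row_scale: bool = True
) -> np.ndarray:
    """Ward hierarchical clustering of per-feature stage series.

    Rows are z-scaled when ``row_scale`` (constant rows become all-zero).
    Returns integer labels 1..n_clusters; deterministic.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if row_scale:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if n_clusters >= X.shape[0]:
        return np.arange(1, X.shape[0] + 1)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")


def adjacent_stage_lfc(series, eps: float = 1e-6) -> np.ndarray:
    """log2 fold changes between adjacent stages of a 4-stage series."""
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or v.size != 4:
        raise ValueError("series must have exactly 4 stages")
    if np.all(v == 0):
        return np.zeros(3)
    if np.any(v + eps <= 0):
        raise ValueError("series must be positive after the pseudocount")
    return np.log2((v[1:] + eps) / (v[:-1] + eps))
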