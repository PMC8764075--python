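"""Contact-matrix data model and core normalisations.

A :class:`ContactMatrix` holds one chromosome's binned cis contact counts as a
dense symmetric array together with its bin table (0-based half-open
coordinates, bin id = floor(start / bin_size)). On top of it this module
provides Knight-Ruiz matrix balancing, library-size normalisation to the
smallest library, the distance-decay expectation, the observed/expected
transform, and distance-stratified contact summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "DecayCurve",
    "ConvergenceError",
    "kr_balance",
    "normalize_to_smallest",
    "expected_by_distance",
    "observed_over_expected",
    "contact_distance_profile",
]


class ConvergenceError(RuntimeError):
    """Raised when iterative balancing fails to reach tolerance."""


def _make_bins(chrom: str, n_bins: int, bin_size: int, chrom_length: int | None = None) -> pd.DataFrame:
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = starts + bin_size
    if chrom_length is not None:
        ends = np.minimum(ends, chrom_length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


@dataclass
class ContactMatrix:
    """Symmetric cis contact matrix for a single chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    bin_size : bin width in bp.
    counts : (n, n) symmetric nonnegative array of contact counts.
    bins : bin table (chrom/start/end); generated if omitted.
    weights : per-bin balancing weights, NaN for filtered bins.
    oe : observed/expected values, set by :func:`observed_over_expected`.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    bins: pd.DataFrame | None = None
    weights: np.ndarray | None = None
    oe: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("counts must be symmetric")
        if self.bins is None:
            self.bins = _make_bins(self.chrom, self.n_bins, self.bin_size)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_pairs(self) -> float:
        """Total contact pairs: upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())

    def balanced(self) -> np.ndarray:
        """diag(w) . counts . diag(w); rows of filtered bins are NaN."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run kr_balance first")
        w = self.weights
        return self.counts * np.outer(w, w)

    def values(self, use: str = "auto") -> np.ndarray:
        """Matrix values: 'raw', 'balanced', or 'auto' (balanced if available)."""
        if use == "raw" or (use == "auto" and self.weights is None):
            return self.counts
        if use in ("balanced", "auto"):
            return self.balanced()
        raise ValueError(f"unknown matrix value choice: {use!r}")

    def copy_with(self, **kw) -> "ContactMatrix":
        args = dict(
            chrom=self.chrom, bin_size=self.bin_size, counts=self.counts,
            bins=self.bins, weights=self.weights, oe=self.oe,
            provenance=dict(self.provenance),
        )
        args.update(kw)
        return ContactMatrix(**args)


@dataclass
class DecayCurve:
    """Expected contact value per genomic separation (one bin-size step)."""

    chrom: str
    bin_size: int
    expected: np.ndarray  # index = separation in bins

    def at_distance_bins(self, d: np.ndarray | int) -> np.ndarray:
        d = np.asarray(d)
        if np.any(d >= len(self.expected)) or np.any(d < 0):
            raise ValueError("distance outside the fitted decay curve")
        return self.expected[d]


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

def _kr_core(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration for x with x*(Ax) = e.

    Follows the bnewt algorithm of Knight & Ruiz (IMA J. Numer. Anal. 2013):
    an inexact Newton method with conjugate-gradient inner solves and a
    delta/Delta safeguard box.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    n_total = 0

    while rout > stop_tol**2 and n_total < max_iter:
        k = 0
        y = e.copy()
        inner_tol = max(rout * eta**2, stop_tol**2)
        # CG for the Newton step
        Z = rk / v
        p = Z.copy()
        rho_km1 = rk @ Z
        while rho_km1 > inner_tol:
            k += 1
            if k > 200:
                break
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            beta = rho_km1 / rho_km2
            p = Z + beta * p
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        n_total += k + 1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, stop_tol / res_norm if res_norm > 0 else etamax), etamax)

    if rout > stop_tol**2:
        raise ConvergenceError("Knight-Ruiz iteration did not converge")
    return x


def kr_balance(
    matrix: ContactMatrix,
    filter_low_count_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 3000,
) -> np.ndarray:
    """Knight-Ruiz balancing weights for a contact matrix.

    Bins whose marginal is zero, or strictly below the
    ``filter_low_count_fraction`` quantile of the positive marginals, are
    filtered out (NaN weight). For the remaining bins the returned weights w
    satisfy row sums of diag(w) M diag(w) = 1 within ``tol``.

    The weights are also stored on ``matrix.weights``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = matrix.counts
    marg = M.sum(axis=1)
    keep = marg > 0
    if filter_low_count_fraction > 0 and keep.any():
        cut = np.quantile(marg[keep], filter_low_count_fraction)
        keep &= ~(marg < cut)
    if not keep.any():
        raise ConvergenceError(f"no usable bins on {matrix.chrom}")
    sub = M[np.ix_(keep, keep)]
    # scale so the mean row sum is ~1; improves conditioning, undone below
    scale = sub.sum(axis=1).mean()
    try:
        x = _kr_core(sub / scale, tol=tol, max_iter=max_iter)
    except ConvergenceError as err:
        raise ConvergenceError(f"{err} on chromosome {matrix.chrom}") from None
    weights = np.full(matrix.n_bins, np.nan)
    weights[keep] = x / np.sqrt(scale)
    matrix.weights = weights
    matrix.provenance["balancing"] = {"method": "KR", "tol": tol,
                                      "filter_low_count_fraction": filter_low_count_fraction}
    return weights


# ---------------------------------------------------------------------------
# Library-size normalisation
# ---------------------------------------------------------------------------

def normalize_to_smallest(matrices: list[ContactMatrix]) -> list[ContactMatrix]:
    """Scale each library down to the smallest library's total pair count.

    Every matrix is multiplied by (min total) / (its total); the smallest
    library is returned unchanged (scale factor exactly 1).
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to normalize")
    ref = matrices[0].bins[["start", "end"]]
    for m in matrices[1:]:
        if m.bin_size != matrices[0].bin_size or not m.bins[["start", "end"]].equals(ref):
            raise ValueError("matrices must share an identical bin table")
    totals = np.array([m.total_pairs for m in matrices])
    if np.any(totals <= 0):
        raise ValueError("cannot normalize an empty library")
    smallest = totals.min()
    out = []
    for m, t in zip(matrices, totals):
        factor = smallest / t
        scaled = m.counts if factor == 1.0 else m.counts * factor
        mm = m.copy_with(counts=scaled, oe=None)
        mm.provenance["normalized_to_smallest"] = factor
        out.append(mm)
    return out


# ---------------------------------------------------------------------------
# Distance decay and observed/expected
# ---------------------------------------------------------------------------

def _diag_stats(values: np.ndarray):
    """Per-separation sum, count of finite entries, and mean."""
    n = values.shape[0]
    sums = np.zeros(n)
    cnts = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        ok = np.isfinite(diag)
        sums[d] = diag[ok].sum()
        cnts[d] = ok.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts > 0, sums / cnts, np.nan)
    return sums, cnts, means


def expected_by_distance(matrix: ContactMatrix, use: str = "auto") -> DecayCurve:
    """Mean contact value at each genomic separation (NA-aware).

    ``use`` selects raw or balanced values; 'auto' takes balanced values when
    weights are present. The denominator at each separation is the number of
    valid (finite) bin pairs.
    """
    if matrix.n_bins == 0:
        raise ValueError("empty matrix")
    vals = matrix.values(use)
    _, _, means = _diag_stats(vals)
    matrix.provenance["expected_from"] = "balanced" if (
        use == "balanced" or (use == "auto" and matrix.weights is not None)) else "raw"
    return DecayCurve(chrom=matrix.chrom, bin_size=matrix.bin_size, expected=means)


def observed_over_expected(
    matrix: ContactMatrix, curve: DecayCurve | None = None, use: str = "auto"
) -> ContactMatrix:
    """Divide each pixel by the expected value at its separation.

    Pixels whose expectation is zero or undefined become NaN; zero observed at
    a positive expectation gives exactly 0. Returns the matrix with ``oe``
    set (in place) and also returns it for chaining.
    """
    if curve is None:
        curve = expected_by_distance(matrix, use=use)
    vals = matrix.values(use)
    n = matrix.n_bins
    if len(curve.expected) < n:
        raise ValueError("decay curve does not cover all distances in the matrix")
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp = curve.expected[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, vals / exp, np.nan)
    matrix.oe = oe
    return matrix


def contact_distance_profile(
    matrix: ContactMatrix,
    short_range_bp: int = 2_000_000,
    long_range_bp: int = 10_000_000,
) -> dict:
    """Cumulative contact-count distribution over genomic distance.

    Uses raw counts at separations of at least one bin (self-pairs on the
    diagonal are not distances). Returns the distances (bp), the nondecreasing
    cumulative fraction reaching 1 at the maximum distance, and the fraction
    of counts in the short (0, short_range_bp] and long
    (short_range_bp, long_range_bp] ranges among counts within long_range_bp.
    """
    if matrix.n_bins == 0:
        raise ValueError("empty matrix")
    sums, _, _ = _diag_stats(matrix.counts)
    sums = sums[1:]  # drop d=0
    if sums.sum() == 0:
        raise ValueError("matrix has no off-diagonal counts")
    dist_bp = (np.arange(1, matrix.n_bins)) * matrix.bin_size
    cum = np.cumsum(sums) / sums.sum()
    in_short = dist_bp <= short_range_bp
    in_long = (dist_bp > short_range_bp) & (dist_bp <= long_range_bp)
    denom = sums[in_short | in_long].sum()
    short_frac = sums[in_short].sum() / denom if denom > 0 else np.nan
    long_frac = sums[in_long].sum() / denom if denom > 0 else np.nan
    return {
        "distance_bp": dist_bp,
        "cumulative_fraction": cum,
        "short_range_fraction": float(short_frac),
        "long_range_fraction": float(long_frac),
    }
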