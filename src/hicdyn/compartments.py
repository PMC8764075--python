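"""A/B compartment calling at 100 kb and four-stage flip classification.

Compartments are called from the leading eigenvector of the Pearson
correlation matrix of the observed/expected map; the eigenvector sign is
oriented per chromosome so that A-labelled bins have the higher mean gene
density. Across the four developmental stages each bin's label sequence is
classified as stable-A, stable-B, A-to-B, B-to-A, or transient (changes in
both directions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, observed_over_expected

__all__ = ["CompartmentTrack", "call_compartments", "classify_flips"]

FLIP_CATEGORIES = ("stable-A", "stable-B", "A-to-B", "B-to-A", "transient")


@dataclass
class CompartmentTrack:
    """Per-bin eigenvector values and A/B labels for one chromosome/stage."""

    chrom: str
    bin_size: int
    eigenvector: np.ndarray  # NaN for filtered/degenerate bins
    labels: np.ndarray       # object array of 'A' / 'B' / None
    gene_density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.labels)) * self.bin_size
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": starts,
            "end": starts + self.bin_size,
            "eigenvector": self.eigenvector,
            "label": [l if l is not None else "NA" for l in self.labels],
        })


def call_compartments(
    oe_matrix_100kb: ContactMatrix,
    gene_density: np.ndarray,
    min_eig_variance: float = 1e-10,
) -> CompartmentTrack:
    """Call A/B compartments from a 100 kb observed/expected matrix.

    Bins whose obs/exp row is all-NaN or has zero variance are excluded from
    the correlation matrix and labelled NA. If the remaining signal is
    degenerate (near-zero eigenvector variance, e.g. a uniform matrix) the
    whole chromosome is returned NA rather than assigning arbitrary signs.
    """
    m = oe_matrix_100kb
    if m.oe is None:
        observed_over_expected(m)
    n = m.n_bins
    gene_density = np.asarray(gene_density, dtype=float)
    if gene_density.shape[0] != n:
        raise ValueError("gene density length must match bin count")
    eig = np.full(n, np.nan)
    labels = np.array([None] * n, dtype=object)

    oe = m.oe
    row_ok = np.isfinite(oe).sum(axis=1) >= 2
    row_var = np.zeros(n)
    masked = np.where(np.isfinite(oe), oe, np.nan)
    row_var[row_ok] = np.nanvar(masked[row_ok], axis=1)
    valid = row_ok & (row_var > 0)
    if valid.sum() >= 3:
        sub = oe[np.ix_(valid, valid)]
        sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
        corr = np.corrcoef(sub)
        if np.all(np.isfinite(corr)):
            evals, evecs = np.linalg.eigh(corr)
            v = evecs[:, -1]
            if np.var(v) > min_eig_variance:
                eig[valid] = v
                lab = np.where(v > 0, "A", np.where(v < 0, "B", None))
                labels[valid] = lab
                # orient: A must be the gene-dense arm
                a = labels == "A"
                b = labels == "B"
                if a.any() and b.any():
                    if np.mean(gene_density[a]) < np.mean(gene_density[b]):
                        eig[valid] = -v
                        labels[a], labels[b] = "B", "A"
    return CompartmentTrack(m.chrom, m.bin_size, eig, labels, gene_density)


def _classify_sequence(seq: list[str]) -> str:
    a2b = any(p == "A" and q == "B" for p, q in zip(seq, seq[1:]))
    b2a = any(p == "B" and q == "A" for p, q in zip(seq, seq[1:]))
    if not a2b and not b2a:
        return "stable-A" if seq[0] == "A" else "stable-B"
    if a2b and b2a:
        return "transient"
    return "A-to-B" if a2b else "B-to-A"


def classify_flips(tracks: list[CompartmentTrack]) -> tuple[pd.DataFrame, dict]:
    """Classify each bin's compartment trajectory across four stages.

    A bin with no label change is stable-A/stable-B; a bin whose changes all
    go one way is A-to-B or B-to-A; a bin changing in both directions is
    transient. Bins NA in any stage are excluded from the denominator. The
    flip fraction is (A-to-B + B-to-A + transient) / classified bins.
    """
    if len(tracks) != 4:
        raise ValueError("flip classification is defined over exactly 4 stages")
    n = len(tracks[0].labels)
    if any(len(t.labels) != n for t in tracks):
        raise ValueError("stages must share the same bins")
    cats = np.array([None] * n, dtype=object)
    for i in range(n):
        seq = [t.labels[i] for t in tracks]
        if any(l not in ("A", "B") for l in seq):
            continue
        cats[i] = _classify_sequence(seq)
    frame = tracks[0].to_frame()[["chrom", "start", "end"]].copy()
    frame["category"] = [c if c is not None else "NA" for c in cats]
    counts = {c: int((cats == c).sum()) for c in FLIP_CATEGORIES}
    classified = sum(counts.values())
    flips = counts["A-to-B"] + counts["B-to-A"] + counts["transient"]
    summary = {
        "counts": counts,
        "classified_bins": classified,
        "flip_fraction": flips / classified if classified else float("nan"),
    }
    return frame, summary
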