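"""Plain-text genomic formats: bins+triplet contact matrices (TSV), BED6,
bedGraph, BEDPE, and gene/expression tables. All coordinates are 0-based
half-open."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix

__all__ = [
    "write_matrix", "read_matrix",
    "write_bed", "read_bed",
    "write_bedgraph", "read_bedgraph",
    "write_bedpe",
]


def write_matrix(matrix: ContactMatrix, bins_path, triplets_path) -> None:
    """Write a contact matrix as a bins table + upper-triangle triplets."""
    matrix.bins.to_csv(bins_path, sep="\t", index=False)
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    nz = vals != 0
    trip = pd.DataFrame({"bin1_id": iu[0][nz], "bin2_id": iu[1][nz], "count": vals[nz]})
    trip.to_csv(triplets_path, sep="\t", index=False)


def read_matrix(bins_path, triplets_path) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t")
    trip = pd.read_csv(triplets_path, sep="\t")
    n = len(bins)
    counts = np.zeros((n, n))
    i = trip["bin1_id"].to_numpy(int)
    j = trip["bin2_id"].to_numpy(int)
    counts[i, j] = trip["count"].to_numpy(float)
    counts[j, i] = counts[i, j]
    chrom = str(bins["chrom"].iloc[0])
    bin_size = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts, bins=bins)


def write_bed(df: pd.DataFrame, path, score_col: str | None = "score") -> None:
    """BED6; the signal (if any) goes in the score column."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["name"] if "name" in df else [f"peak_{i}" for i in range(len(df))],
        "score": df[score_col] if score_col and score_col in df else 0,
        "strand": df["strand"] if "strand" in df else ".",
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def write_bedpe(loops: pd.DataFrame, path) -> None:
    cols = pd.DataFrame({
        "chrom1": loops["chrom"], "start1": loops["start1"], "end1": loops["end1"],
        "chrom2": loops["chrom"], "start2": loops["start2"], "end2": loops["end2"],
    })
    for extra in ("count", "enrichment", "p_adj", "class", "subtype"):
        if extra in loops:
            cols[extra] = loops[extra]
    cols.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
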