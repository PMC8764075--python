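"""Regulatory annotation and multi-omic integration.

Promoters are TSS +/- 5 kb windows; enhancers are H3K27ac peaks that do not
touch any promoter window (whole-peak exclusion). Loop anchors are labelled
promoter (precedence) / enhancer / other, loops classified E-E / E-P / P-P,
and E-P loops subtyped by transcription-factor occupancy on the promoter
anchor, the enhancer anchor, or both. Genes are assigned to a loop when their
TSS lies within 20 kb of an anchor. Peak-restricted ChIP signals, boundary
meta-profiles, and four-stage expression trend classes live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "RegulatoryAnnotation",
    "build_annotation",
    "classify_interaction",
    "tf_engagement",
    "engagement_summary",
    "assign_genes",
    "signal_on_regions",
    "boundary_metaprofile",
    "expression_trend",
]

PROMOTER_HALF_WIDTH = 5_000
GENE_ASSIGN_MAX_DIST = 20_000


def _tree(df: pd.DataFrame, data_col: str | None = None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        t = IntervalTree()
        for _, r in grp.iterrows():
            if r["end"] > r["start"]:
                t[r["start"]:r["end"]] = r[data_col] if data_col else None
        trees[chrom] = t
    return trees


@dataclass
class RegulatoryAnnotation:
    """Promoter and enhancer interval sets for one stage."""

    promoters: pd.DataFrame  # chrom, start, end, gene
    enhancers: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        self._ptree = _tree(self.promoters)
        self._etree = _tree(self.enhancers)

    def overlaps_promoter(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self._ptree and bool(self._ptree[chrom][start:end])

    def overlaps_enhancer(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self._etree and bool(self._etree[chrom][start:end])


def build_annotation(genes: pd.DataFrame, h3k27ac_peaks: pd.DataFrame) -> RegulatoryAnnotation:
    """Derive promoters (TSS +/- 5 kb) and distal enhancers from peaks.

    A peak overlapping any promoter window by even 1 bp is excluded entirely
    from the enhancer set.
    """
    prom = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(0, genes["tss"] - PROMOTER_HALF_WIDTH),
        "end": genes["tss"] + PROMOTER_HALF_WIDTH,
        "gene": genes["gene"],
    })
    ptree = _tree(prom)
    keep = []
    for _, pk in h3k27ac_peaks.iterrows():
        t = ptree.get(pk["chrom"])
        keep.append(not (t and t[pk["start"]:pk["end"]]))
    enh = h3k27ac_peaks.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    return RegulatoryAnnotation(promoters=prom, enhancers=enh)


def _anchor_label(ann: RegulatoryAnnotation, chrom: str, start: int, end: int) -> str:
    if ann.overlaps_promoter(chrom, start, end):
        return "P"  # promoter precedence keeps the classes a partition
    if ann.overlaps_enhancer(chrom, start, end):
        return "E"
    return "other"


def classify_interaction(loop: pd.Series, annotation: RegulatoryAnnotation) -> dict:
    """Label both anchors and classify the loop as E-E / E-P / P-P / other."""
    l1 = _anchor_label(annotation, loop["chrom"], loop["start1"], loop["end1"])
    l2 = _anchor_label(annotation, loop["chrom"], loop["start2"], loop["end2"])
    pair = sorted([l1, l2])
    if pair == ["E", "E"]:
        cls = "E-E"
    elif pair == ["E", "P"]:
        cls = "E-P"
    elif pair == ["P", "P"]:
        cls = "P-P"
    else:
        cls = "other"
    return {"anchor1_label": l1, "anchor2_label": l2, "class": cls}


def tf_engagement(
    loop: pd.Series, labels: dict, tf_peaks: pd.DataFrame,
) -> dict:
    """TF engagement of an E-P interaction.

    Engaged iff a TF peak overlaps at least one anchor; the subtype records
    whether occupancy falls on the promoter anchor, the enhancer anchor, or
    both. Raises on non-E-P interactions.
    """
    if labels["class"] != "E-P":
        raise ValueError("TF engagement subtyping is defined for E-P interactions only")
    ttree = _tree(tf_peaks)
    chrom = loop["chrom"]

    def hit(start, end):
        return chrom in ttree and bool(ttree[chrom][start:end])

    on1 = hit(loop["start1"], loop["end1"])
    on2 = hit(loop["start2"], loop["end2"])
    anchor_roles = {
        "P": "promoter", "E": "enhancer",
    }
    hits = set()
    if on1:
        hits.add(anchor_roles[labels["anchor1_label"]])
    if on2:
        hits.add(anchor_roles[labels["anchor2_label"]])
    if not hits:
        return {"engaged": False, "subtype": "none"}
    if hits == {"promoter"}:
        sub = "promoter-only"
    elif hits == {"enhancer"}:
        sub = "enhancer-only"
    else:
        sub = "both"
    return {"engaged": True, "subtype": sub}


def engagement_summary(interactions: pd.DataFrame) -> dict:
    """Per-class counts and TF-engaged fractions of a classified loop table."""
    out = {"class_counts": interactions["class"].value_counts().to_dict()}
    ep = interactions[interactions["class"] == "E-P"]
    if len(ep) and "engaged" in interactions:
        engaged = ep["engaged"].astype(bool)
        out["ep_engaged_fraction"] = float(engaged.mean())
        out["ep_engaged_count"] = int(engaged.sum())
        sub = ep.loc[engaged, "subtype"].value_counts().to_dict() if engaged.any() else {}
        out["ep_subtype_counts"] = sub
    else:
        out["ep_engaged_fraction"] = float("nan")
        out["ep_subtype_counts"] = {}
    return out


def assign_genes(
    loop: pd.Series, genes: pd.DataFrame, max_dist: int = GENE_ASSIGN_MAX_DIST,
) -> list[str]:
    """Genes whose TSS lies within ``max_dist`` of either anchor interval."""
    g = genes[genes["chrom"] == loop["chrom"]]
    out = []
    for _, row in g.iterrows():
        tss = row["tss"]
        d = min(
            _interval_distance(tss, loop["start1"], loop["end1"]),
            _interval_distance(tss, loop["start2"], loop["end2"]),
        )
        if d <= max_dist:
            out.append(row["gene"])
    return out


def _interval_distance(pos: int, start: int, end: int) -> int:
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - (end - 1)


def _intersect_length_weighted(
    coverage: pd.DataFrame, pieces: list[tuple[str, int, int]],
) -> float:
    """Integral of per-bp coverage over a list of (chrom,start,end) pieces."""
    total = 0.0
    cov_by_chrom = {c: g for c, g in coverage.groupby("chrom")}
    for chrom, s, e in pieces:
        g = cov_by_chrom.get(chrom)
        if g is None:
            continue
        ov_s = np.maximum(g["start"].to_numpy(), s)
        ov_e = np.minimum(g["end"].to_numpy(), e)
        span = np.clip(ov_e - ov_s, 0, None)
        total += float((span * g["value"].to_numpy()).sum())
    return total


def _region_peak_pieces(peaks: pd.DataFrame, chrom: str, start: int, end: int):
    pieces = []
    pk = peaks[peaks["chrom"] == chrom]
    s = np.maximum(pk["start"].to_numpy(), start)
    e = np.minimum(pk["end"].to_numpy(), end)
    for a, b in zip(s, e):
        if b > a:
            pieces.append((chrom, int(a), int(b)))
    return pieces


def signal_on_regions(
    coverage: pd.DataFrame,
    peaks: pd.DataFrame,
    regions: pd.DataFrame,
    library_size: float,
) -> pd.DataFrame:
    """Peak-restricted, per-million signal over regions.

    Coverage is a bedGraph-style table whose value is reads per bp, so the
    integral over an interval is its read count. Only coverage inside the
    mark's peaks contributes; the sum is scaled by 1e6 / library_size.
    Regions intersecting no peak score exactly 0.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    vals = []
    for _, r in regions.iterrows():
        pieces = _region_peak_pieces(peaks, r["chrom"], r["start"], r["end"])
        vals.append(_intersect_length_weighted(coverage, pieces) * 1e6 / library_size)
    out = regions.copy()
    out["signal"] = vals
    return out


def boundary_metaprofile(
    coverage: pd.DataFrame,
    peaks: pd.DataFrame,
    boundaries: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = 500_000,
    bin_size: int = 10_000,
    library_size: float | None = None,
) -> dict:
    """Mean peak-restricted signal around boundary centres.

    Bins the +/- ``flank`` window around each boundary centre into
    ``bin_size`` offsets (101 bins at the defaults) and averages the
    peak-restricted signal per offset over boundaries. Boundaries whose
    window leaves the chromosome are skipped and counted.
    """
    if len(boundaries) == 0:
        raise ValueError("empty boundary list")
    n_bins = 2 * (flank // bin_size) + 1
    offsets = (np.arange(n_bins) - flank // bin_size) * bin_size
    acc = np.zeros(n_bins)
    used = skipped = 0
    for _, b in boundaries.iterrows():
        center = (b["start"] + b["end"]) // 2
        chrom = b["chrom"]
        if center - flank - bin_size // 2 < 0 or \
                center + flank + bin_size // 2 > chrom_lengths[chrom]:
            skipped += 1
            continue
        for k, off in enumerate(offsets):
            s = int(center + off - bin_size // 2)
            e = int(center + off + bin_size // 2)
            pieces = _region_peak_pieces(peaks, chrom, s, e)
            acc[k] += _intersect_length_weighted(coverage, pieces)
        used += 1
    if used == 0:
        raise ValueError("no boundary has a full window inside its chromosome")
    curve = acc / used
    if library_size:
        curve = curve * 1e6 / library_size
    return {"offset_bp": offsets, "signal": curve, "n_used": used, "n_skipped": skipped}


def expression_trend(stage_means, eps: float = 0.25) -> str:
    """Classify a 4-stage expression series as up / down / transient / flat.

    Works on log2(TPM/10 + 1) stage means with a dead band of ``eps`` log2
    units: deltas within +/- eps are noise; all-noise series are flat; series
    moving only upward (at least one delta > eps) are up, only downward are
    down, and mixed-direction series are transient.
    """
    v = np.asarray(stage_means, dtype=float)
    if v.size != 4 or not np.all(np.isfinite(v)):
        raise ValueError("need 4 finite stage means")
    d = np.diff(v)
    if np.all(np.abs(d) <= eps):
        return "flat"
    if np.all(d >= 0) and np.any(d > eps):
        return "up"
    if np.all(d <= 0) and np.any(d < -eps):
        return "down"
    return "transient"
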