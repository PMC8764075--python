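"""Four-stage synthetic genomes with planted 3D architecture, chromatin
marks, TF occupancy, and expression.

The generator plants, per stage, the structures the downstream statistics
assume: A/B compartment labels at 100 kb with a controlled flip fraction and
flip taxonomy, TADs tiling each chromosome with stage trends in intra-TAD
enrichment, loops with increasing / decreasing / ephemeral / stable strength
trajectories, enhancer and promoter elements carrying stage-dependent mark
intensities, TF occupancy on loop anchors, and gene expression that follows
increasing loops with a one-stage lag. Contact maps are Poisson samples of a
power-law distance-decay baseline multiplied by compartment concordance,
intra-TAD enrichment, and loop factors.

The ground truth is serialisable to JSON and is the reference for all
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from . import io as hio

__all__ = [
    "GenomeModel",
    "ArchitectureTruth",
    "SyntheticOmics",
    "simulate_genome",
    "simulate_architecture",
    "simulate_contact_matrix",
    "simulate_chip_and_expression",
    "DEFAULT_STAGES",
]

DEFAULT_STAGES = ("eAEC", "HEC", "pre-HSC", "LT-HSC")
COMPARTMENT_BIN = 100_000
LOOP_ANCHOR_BIN = 10_000

# study-condition defaults
DEFAULT_FLIP_FRACTION = 0.1078      # observed genome-wide flip fraction
DEFAULT_COMP_FACTOR = 1.5           # same/different-label contact modulation
DEFAULT_DECAY_EXPONENT = 1.0
DEFAULT_EP_ENGAGED_FRACTION = 0.409  # TF-bound share of E-P interactions
DEFAULT_CELLS_PER_STAGE = (42, 33, 50, 16)

TRAJECTORY_MULTIPLIERS = {
    "increasing": (1.0, 2.0, 3.5, 5.0),
    "decreasing": (5.0, 3.5, 2.0, 1.0),
    "ephemeral": (1.0, 5.0, 5.0, 1.0),
    "stable": (5.0, 5.0, 5.0, 5.0),
}
DEFAULT_TRAJECTORY_MIX = {
    "increasing": 0.3, "decreasing": 0.3, "ephemeral": 0.2, "stable": 0.2,
}
MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")


@dataclass
class GenomeModel:
    """Coordinate frame: chromosomes, bin size, and gene TSS records."""

    chroms: dict[str, int]
    bin_size: int
    genes: pd.DataFrame  # gene, chrom, tss, strand
    seed: int = 0

    def n_bins(self, chrom: str, bin_size: int | None = None) -> int:
        bs = bin_size or self.bin_size
        return -(-self.chroms[chrom] // bs)  # last partial bin kept

    def to_dict(self) -> dict:
        return {
            "chroms": self.chroms, "bin_size": self.bin_size, "seed": self.seed,
            "genes": self.genes.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeModel":
        return cls(chroms=dict(d["chroms"]), bin_size=int(d["bin_size"]),
                   genes=pd.DataFrame(d["genes"]), seed=int(d["seed"]))


def simulate_genome(
    n_chroms: int = 1,
    chrom_length_bp: int = 20_000_000,
    bin_size_bp: int = 40_000,
    n_genes: int = 200,
    seed: int = 0,
) -> GenomeModel:
    """Uniform-random gene placement on equal-length chromosomes."""
    if min(n_chroms, chrom_length_bp, bin_size_bp, n_genes) <= 0:
        raise ValueError("all genome parameters must be positive")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": int(chrom_length_bp) for i in range(n_chroms)}
    names = list(chroms)
    rows = []
    for g in range(n_genes):
        chrom = names[int(rng.integers(len(names)))]
        tss = int(rng.integers(0, chroms[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene_{g}", chrom, tss, strand))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])
    genes = genes.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    return GenomeModel(chroms=chroms, bin_size=int(bin_size_bp), genes=genes, seed=seed)


@dataclass
class ArchitectureTruth:
    """Planted per-stage architecture and regulatory elements."""

    stages: tuple[str, ...]
    comp_bin_size: int
    compartments: dict[str, np.ndarray]      # chrom -> (n_stages, n_comp_bins) of 'A'/'B'
    flip_category: dict[str, np.ndarray]     # chrom -> per-bin category string
    tads: pd.DataFrame                       # chrom, start, end, trend
    tad_enrichment: np.ndarray               # (n_tads, n_stages)
    loops: pd.DataFrame                      # chrom, anchor1, anchor2, trajectory, class, engaged, subtype
    loop_multipliers: np.ndarray             # (n_loops, n_stages)
    elements: pd.DataFrame                   # chrom, start, end, kind, gene, loop_id, anchor_role
    mark_intensity: dict[str, np.ndarray]    # mark -> (n_elements, n_stages)
    tf_occupied: np.ndarray = field(default=None)  # (n_elements, n_stages) bool

    @property
    def flip_fraction(self) -> float:
        flipped = total = 0
        for chrom, labels in self.compartments.items():
            changed = (labels != labels[0]).any(axis=0)
            flipped += int(changed.sum())
            total += labels.shape[1]
        return flipped / total

    def tad_boundaries(self, chrom: str) -> np.ndarray:
        """Internal boundary positions (bp) of the TAD tiling on a chromosome."""
        t = self.tads[self.tads["chrom"] == chrom].sort_values("start")
        return t["start"].to_numpy()[1:]

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "comp_bin_size": self.comp_bin_size,
            "compartments": {c: a.tolist() for c, a in self.compartments.items()},
            "flip_category": {c: a.tolist() for c, a in self.flip_category.items()},
            "tads": self.tads.to_dict(orient="list"),
            "tad_enrichment": self.tad_enrichment.tolist(),
            "loops": self.loops.to_dict(orient="list"),
            "loop_multipliers": self.loop_multipliers.tolist(),
            "elements": self.elements.to_dict(orient="list"),
            "mark_intensity": {m: a.tolist() for m, a in self.mark_intensity.items()},
            "tf_occupied": self.tf_occupied.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureTruth":
        return cls(
            stages=tuple(d["stages"]),
            comp_bin_size=int(d["comp_bin_size"]),
            compartments={c: np.array(a, dtype=object) for c, a in d["compartments"].items()},
            flip_category={c: np.array(a, dtype=object) for c, a in d["flip_category"].items()},
            tads=pd.DataFrame(d["tads"]),
            tad_enrichment=np.array(d["tad_enrichment"], dtype=float),
            loops=pd.DataFrame(d["loops"]),
            loop_multipliers=np.array(d["loop_multipliers"], dtype=float),
            elements=pd.DataFrame(d["elements"]),
            mark_intensity={m: np.array(a, dtype=float) for m, a in d["mark_intensity"].items()},
            tf_occupied=np.array(d["tf_occupied"], dtype=bool),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path) -> "ArchitectureTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

def _mix_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Split n into class counts proportional to mix (largest remainder)."""
    keys = list(mix)
    raw = np.array([mix[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % len(keys)]] += 1
    return dict(zip(keys, base))


def simulate_architecture(
    genome: GenomeModel,
    stage_count: int = 4,
    flip_fraction: float = DEFAULT_FLIP_FRACTION,
    tad_count: int = 10,
    loop_count: int = 30,
    trajectory_mix: dict[str, float] | None = None,
    ep_engaged_fraction: float = DEFAULT_EP_ENGAGED_FRACTION,
    min_loop_separation: int = 200_000,
    max_loop_separation: int = 1_500_000,
    min_tad_bins: int = 8,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    seed: int = 0,
) -> ArchitectureTruth:
    """Plant compartments, TADs, loops, elements, and TF occupancy."""
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must be in [0, 1]")
    trajectory_mix = dict(trajectory_mix or DEFAULT_TRAJECTORY_MIX)
    if abs(sum(trajectory_mix.values()) - 1.0) > 1e-9:
        raise ValueError("trajectory_mix must sum to 1")
    if stage_count != len(stages):
        stages = tuple(f"stage{i}" for i in range(stage_count))
    rng = np.random.default_rng(seed)
    n_stages = stage_count

    compartments: dict[str, np.ndarray] = {}
    flip_category: dict[str, np.ndarray] = {}
    tad_rows, tad_enr = [], []
    loop_rows, loop_mult = [], []
    el_rows, intens = [], {m: [] for m in MARKS}
    tf_rows = []

    for chrom, length in genome.chroms.items():
        # --- TADs tiling the chromosome; edges snap to the lcm of the genome
        # bin and the 100 kb compartment grid so compartment switches can sit
        # exactly on TAD boundaries (as they do in real maps)
        nb = genome.n_bins(chrom)
        if tad_count > nb:
            raise ValueError("tad_count exceeds the chromosome bin count")
        unit = int(np.lcm(genome.bin_size, COMPARTMENT_BIN) // genome.bin_size)
        n_units = nb // unit
        min_units = max(1, -(-min_tad_bins // unit))
        spare = n_units - tad_count * min_units
        if spare < 0:
            raise ValueError("chromosome too short for tad_count TADs of minimum size")
        lens = (min_units + rng.multinomial(spare, [1.0 / tad_count] * tad_count)) * unit
        edges = np.concatenate([[0], np.cumsum(lens)]) * genome.bin_size
        edges[-1] = length
        trends = [("stable", "increasing", "decreasing")[i % 3] for i in range(tad_count)]

        # --- compartments at 100 kb: blocks are unions of consecutive TADs,
        # the gene-dense arm is A
        ncb = -(-length // COMPARTMENT_BIN)
        tad_edges_cb = (edges // COMPARTMENT_BIN).astype(int)
        gd = np.zeros(ncb)
        tss = genome.genes.loc[genome.genes["chrom"] == chrom, "tss"].to_numpy()
        np.add.at(gd, np.minimum(tss // COMPARTMENT_BIN, ncb - 1), 1)
        # Gene-dense blocks become A: the generator reproduces the real
        # coupling between compartment identity and gene density that the
        # eigenvector sign-orientation rule relies on. The block segmentation
        # is redrawn until the A-vs-B density gap is clearly resolvable
        # (>= 2 SD of the difference-in-means noise for Poisson gene counts),
        # otherwise the orientation of real maps would be undefined too.
        min_gap = 2.0 * np.sqrt(gd.mean() * 4.0 / ncb) if ncb else 0.0
        best: tuple[float, np.ndarray] | None = None
        for _draw in range(50):
            seg_bounds = [tad_edges_cb[0]]
            for i in range(tad_count):
                stop = ncb if i == tad_count - 1 else tad_edges_cb[i + 1]
                if rng.random() < 0.5 or i == tad_count - 1:  # mean two TADs/block
                    seg_bounds.append(stop)
            segs = list(zip(seg_bounds[:-1], seg_bounds[1:]))
            if len(segs) == 1:  # degenerate: keep both labels represented
                s, e = segs[0]
                segs = [(s, (s + e) // 2), ((s + e) // 2, e)]
            seg_dens = [gd[s:e].mean() if e > s else 0.0 for s, e in segs]
            order = sorted(range(len(segs)), key=lambda i: (-seg_dens[i], i))
            base = np.array(["B"] * ncb, dtype=object)
            a_bins = 0
            for i in order:
                s, e = segs[i]
                base[s:e] = "A"
                a_bins += e - s
                if a_bins >= ncb // 2:
                    break
            is_a = base == "A"
            if is_a.all() or not is_a.any():
                gap = -np.inf
            else:
                gap = gd[is_a].mean() - gd[~is_a].mean()
            if best is None or gap > best[0]:
                best = (gap, base)
            if gap >= min_gap:
                break
        base = best[1]

        labels = np.tile(base, (n_stages, 1)).astype(object)
        cats = np.where(base == "A", "stable-A", "stable-B").astype(object)
        n_flip = int(round(flip_fraction * ncb))
        # flips happen in short contiguous runs (compartment switches are
        # regional; single-bin flips would be invisible at any depth), kept
        # clear of TAD edges so each planted structure stays separable
        runs: list[tuple[int, int]] = []
        planted = 0
        taken = np.zeros(ncb, dtype=bool)
        attempts = 0
        margin = 3  # comp bins between a flip-run edge and any TAD edge
        while planted < n_flip and attempts < 10_000:
            attempts += 1
            run = min(int(rng.geometric(1 / 3.0)), n_flip - planted)
            s = int(rng.integers(0, ncb - run + 1))
            if taken[s:s + run].any() or len(set(base[s:s + run])) != 1:
                continue
            if np.min(np.abs(tad_edges_cb - s)) < margin or \
                    np.min(np.abs(tad_edges_cb - (s + run))) < margin:
                continue
            taken[s:s + run] = True
            runs.append((s, run))
            planted += run
        for s, run in runs:
            sl = slice(s, s + run)
            other = "B" if base[s] == "A" else "A"
            if rng.random() < 0.5:  # directional flip
                t = int(rng.integers(1, n_stages))
                labels[t:, sl] = other
                cats[sl] = "A-to-B" if base[s] == "A" else "B-to-A"
            else:  # transient: out and back
                t1 = int(rng.integers(1, n_stages - 1))
                t2 = int(rng.integers(t1 + 1, n_stages))
                labels[t1:t2, sl] = other
                cats[sl] = "transient"
        compartments[chrom] = labels
        flip_category[chrom] = cats
        for i in range(tad_count):
            tad_rows.append((chrom, int(edges[i]), int(edges[i + 1]), trends[i]))
            b = rng.uniform(1.9, 2.3)
            # trend ramps stay above ~1.4x so every boundary remains visible
            # at every stage while the connectivity trend is unambiguous
            ramp = {
                "stable": np.ones(n_stages),
                "increasing": np.linspace(0.75, 1.25, n_stages),
                "decreasing": np.linspace(1.25, 0.75, n_stages),
            }[trends[i]]
            tad_enr.append(b * ramp)

        # --- loops on the 10 kb anchor grid
        n_anchor_bins = -(-length // LOOP_ANCHOR_BIN)
        tss_sorted = np.sort(tss)
        tss_bins = np.unique(tss // LOOP_ANCHOR_BIN)
        tss_bins = tss_bins[tss_bins < n_anchor_bins]

        def near_tss(pos, d):
            i = np.searchsorted(tss_sorted, pos)
            lo = tss_sorted[i - 1] if i > 0 else -10**12
            hi = tss_sorted[i] if i < tss_sorted.size else 10**12
            return min(pos - lo, hi - pos) <= d

        # an enhancer anchor interval (10 kb) must not touch any promoter
        # window (TSS +/- 5 kb): overlap happens iff the TSS is within 10 kb
        # of the bin centre, so keep a 10.5 kb clearance
        enh_ok = np.array([
            b for b in range(n_anchor_bins)
            if not near_tss(b * LOOP_ANCHOR_BIN + LOOP_ANCHOR_BIN // 2, 10_500)
        ])
        traj_counts = _mix_counts(loop_count, trajectory_mix)
        traj_list = [t for t, c in traj_counts.items() for _ in range(c)]
        class_counts = _mix_counts(loop_count, {"E-P": 0.5, "E-E": 0.25, "P-P": 0.25})
        class_list = [c for c, k in class_counts.items() for _ in range(k)]
        rng.shuffle(class_list)
        used_anchors: list[int] = []
        min_sep_bins = min_loop_separation // LOOP_ANCHOR_BIN
        max_sep_bins = max_loop_separation // LOOP_ANCHOR_BIN

        def pick_pair(kind1, kind2):
            for _ in range(2000):
                pool1 = tss_bins if kind1 == "P" else enh_ok
                a1 = int(rng.choice(pool1))
                sep = int(rng.integers(min_sep_bins, max_sep_bins + 1))
                a2 = a1 + sep
                if a2 >= n_anchor_bins:
                    continue
                pool2 = tss_bins if kind2 == "P" else enh_ok
                if a2 not in pool2:
                    continue
                if any(abs(a1 - u) < 4 or abs(a2 - u) < 4 for u in used_anchors):
                    continue
                return a1, a2
            return None

        n_ep_target = sum(1 for c in class_list if c == "E-P")
        n_engaged = int(round(ep_engaged_fraction * n_ep_target))
        engaged_flags = [True] * n_engaged + [False] * (n_ep_target - n_engaged)
        rng.shuffle(engaged_flags)
        subtype_cycle = (["promoter-only"] * 3 + ["both"] + ["enhancer-only"])
        ep_seen = 0
        for li, (traj, cls) in enumerate(zip(traj_list, class_list)):
            kinds = {"E-P": ("E", "P"), "E-E": ("E", "E"), "P-P": ("P", "P")}[cls]
            if rng.random() < 0.5:
                kinds = kinds[::-1]
            pair = pick_pair(*kinds)
            if pair is None:
                continue
            a1, a2 = pair
            used_anchors.extend([a1, a2])
            engaged = False
            subtype = "none"
            if cls == "E-P":
                engaged = engaged_flags[ep_seen]
                if engaged:
                    subtype = subtype_cycle[ep_seen % len(subtype_cycle)]
                ep_seen += 1
            loop_rows.append((chrom, int(a1 * LOOP_ANCHOR_BIN), int(a2 * LOOP_ANCHOR_BIN),
                              traj, cls, engaged, subtype))
            loop_mult.append(TRAJECTORY_MULTIPLIERS[traj][:n_stages])

            # elements at the two anchors
            mult = np.asarray(TRAJECTORY_MULTIPLIERS[traj][:n_stages])
            for anchor_pos, kind in ((a1, kinds[0]), (a2, kinds[1])):
                start_bp = anchor_pos * LOOP_ANCHOR_BIN
                tf_here = engaged and (
                    (subtype == "both")
                    or (subtype == "promoter-only" and kind == "P")
                    or (subtype == "enhancer-only" and kind == "E")
                )
                if kind == "P":
                    in_bin = tss[(tss >= start_bp) & (tss < start_bp + LOOP_ANCHOR_BIN)]
                    t = int(in_bin[0])
                    gene = genome.genes[(genome.genes["chrom"] == chrom)
                                        & (genome.genes["tss"] == t)]["gene"].iloc[0]
                    el_rows.append((chrom, max(0, t - 1000), t + 1000, "promoter",
                                    gene, len(loop_rows) - 1, kind))
                    intens["H3K4me3"].append(40.0 * np.ones(n_stages))
                    intens["H3K27ac"].append(30.0 * mult / 5.0)
                    intens["H3K4me1"].append(np.zeros(n_stages))
                    intens["H3K27me3"].append(np.zeros(n_stages))
                else:
                    c = start_bp + LOOP_ANCHOR_BIN // 2
                    el_rows.append((chrom, c - 1000, c + 1000, "enhancer",
                                    "", len(loop_rows) - 1, kind))
                    intens["H3K27ac"].append(50.0 * mult / 5.0)
                    intens["H3K4me1"].append(30.0 * np.ones(n_stages))
                    intens["H3K4me3"].append(np.zeros(n_stages))
                    intens["H3K27me3"].append(np.zeros(n_stages))
                tf_rows.append(np.full(n_stages, tf_here))

        # --- promoter-mark elements at TAD boundaries (H3K4me3 peaks there)
        for bpos in edges[1:-1]:
            el_rows.append((chrom, max(0, int(bpos) - 1000), int(bpos) + 1000,
                            "boundary", "", -1, ""))
            intens["H3K4me3"].append(35.0 * np.ones(n_stages))
            intens["H3K27ac"].append(np.zeros(n_stages))
            intens["H3K4me1"].append(np.zeros(n_stages))
            intens["H3K27me3"].append(np.zeros(n_stages))
            tf_rows.append(np.zeros(n_stages, dtype=bool))

        # --- repressive background in B-compartment bins
        b_bins = np.where(base == "B")[0]
        for b in rng.choice(b_bins, size=min(15, b_bins.size), replace=False):
            s = int(b) * COMPARTMENT_BIN + COMPARTMENT_BIN // 2
            el_rows.append((chrom, s, s + 2000, "repressed", "", -1, ""))
            intens["H3K27me3"].append(20.0 * np.ones(n_stages))
            intens["H3K27ac"].append(np.zeros(n_stages))
            intens["H3K4me1"].append(np.zeros(n_stages))
            intens["H3K4me3"].append(np.zeros(n_stages))
            tf_rows.append(np.zeros(n_stages, dtype=bool))

    truth = ArchitectureTruth(
        stages=stages,
        comp_bin_size=COMPARTMENT_BIN,
        compartments=compartments,
        flip_category=flip_category,
        tads=pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "trend"]),
        tad_enrichment=np.array(tad_enr),
        loops=pd.DataFrame(loop_rows, columns=[
            "chrom", "anchor1", "anchor2", "trajectory", "class", "engaged", "subtype"]),
        loop_multipliers=np.array(loop_mult) if loop_mult else np.zeros((0, n_stages)),
        elements=pd.DataFrame(el_rows, columns=[
            "chrom", "start", "end", "kind", "gene", "loop_id", "anchor_role"]),
        mark_intensity={m: (np.array(v) if v else np.zeros((0, n_stages)))
                        for m, v in intens.items()},
        tf_occupied=np.array(tf_rows) if tf_rows else np.zeros((0, n_stages), dtype=bool),
    )
    return truth


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def _stage_index(truth: ArchitectureTruth, stage) -> int:
    if isinstance(stage, str):
        if stage not in truth.stages:
            raise ValueError(f"unknown stage {stage!r}")
        return truth.stages.index(stage)
    stage = int(stage)
    if not 0 <= stage < len(truth.stages):
        raise ValueError(f"stage index {stage} outside truth")
    return stage


def expected_contact_matrix(
    genome: GenomeModel,
    truth: ArchitectureTruth | None,
    stage,
    chrom: str,
    bin_size: int | None = None,
    decay_exponent: float = DEFAULT_DECAY_EXPONENT,
    comp_factor: float = DEFAULT_COMP_FACTOR,
) -> np.ndarray:
    """Noise-free expected contact intensities (unnormalised)."""
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    bs = bin_size or genome.bin_size
    n = genome.n_bins(chrom, bs)
    idx = np.arange(n)
    lam = (np.abs(np.subtract.outer(idx, idx)) + 1.0) ** (-decay_exponent)
    if truth is None:
        return lam
    s = _stage_index(truth, stage)
    mid = idx * bs + bs // 2
    labels = truth.compartments[chrom][s]
    lab = labels[np.minimum(mid // truth.comp_bin_size, labels.size - 1)]
    same = np.equal.outer(lab, lab)
    lam *= np.where(same, comp_factor, 1.0 / comp_factor)
    tads = truth.tads[truth.tads["chrom"] == chrom]
    for (idx_t, tad) in zip(tads.index, tads.itertuples()):
        inside = (mid >= tad.start) & (mid < tad.end)
        f = truth.tad_enrichment[truth.tads.index.get_loc(idx_t), s]
        lam[np.ix_(inside, inside)] *= f
    loops = truth.loops[truth.loops["chrom"] == chrom]
    for pos, loop in zip(range(len(truth.loops)), truth.loops.itertuples()):
        if loop.chrom != chrom:
            continue
        a1 = int(loop.anchor1 // bs)
        a2 = int(loop.anchor2 // bs)
        if a1 == a2 or a1 >= n or a2 >= n:
            continue
        m = truth.loop_multipliers[pos, s]
        lam[a1, a2] *= m
        lam[a2, a1] *= m
    return lam


def simulate_contact_matrix(
    genome: GenomeModel,
    truth: ArchitectureTruth | None,
    stage,
    depth_pairs: float = 1_000_000,
    decay_exponent: float = DEFAULT_DECAY_EXPONENT,
    seed: int = 0,
    chrom: str | None = None,
    bin_size: int | None = None,
    comp_factor: float = DEFAULT_COMP_FACTOR,
) -> ContactMatrix:
    """Poisson-sample a stage's contact matrix to the requested depth.

    Expected contacts follow distance^(-decay_exponent), modulated by
    compartment concordance (x comp_factor same-label, / comp_factor
    different), intra-TAD enrichment, and loop multipliers, then scaled so the
    expected total (upper triangle) equals ``depth_pairs``. depth_pairs = 0
    returns the all-zero matrix.
    """
    if depth_pairs < 0:
        raise ValueError("depth_pairs must be nonnegative")
    chrom = chrom or next(iter(genome.chroms))
    bs = bin_size or genome.bin_size
    lam = expected_contact_matrix(genome, truth, stage, chrom, bs,
                                  decay_exponent, comp_factor)
    n = lam.shape[0]
    iu = np.triu_indices(n)
    tot = lam[iu].sum()
    if depth_pairs == 0 or tot == 0:
        counts = np.zeros((n, n))
    else:
        lam_u = lam[iu] * (depth_pairs / tot)
        rng = np.random.default_rng(seed)
        draws = rng.poisson(lam_u).astype(float)
        counts = np.zeros((n, n))
        counts[iu] = draws
        counts = counts + np.triu(counts, k=1).T
    cm = ContactMatrix(chrom=chrom, bin_size=bs, counts=counts)
    cm.provenance.update({
        "synthetic": True, "stage": str(stage), "depth_pairs": depth_pairs,
        "decay_exponent": decay_exponent, "comp_factor": comp_factor, "seed": seed,
    })
    return cm


# ---------------------------------------------------------------------------
# ChIP peaks, coverage, expression
# ---------------------------------------------------------------------------

@dataclass
class SyntheticOmics:
    """Per-stage ChIP peaks/coverage, TF peaks, and single-cell expression."""

    peaks: dict          # (stage, mark) -> DataFrame(chrom,start,end,name,score)
    coverage: dict       # (stage, mark) -> DataFrame(chrom,start,end,value)
    tf_peaks: dict       # stage -> DataFrame
    library_sizes: dict  # (stage, mark) -> float reads
    expression: pd.DataFrame  # genes x cells, log2(TPM/10+1) scale
    cell_stage: pd.Series     # cell -> stage


def simulate_chip_and_expression(
    genome: GenomeModel,
    truth: ArchitectureTruth,
    seed: int = 0,
    reads_per_intensity: float = 10.0,
    cells_per_stage: tuple[int, ...] = DEFAULT_CELLS_PER_STAGE,
    loop_expression_effect: float = 2.0,
    expression_noise_sd: float = 0.4,
) -> SyntheticOmics:
    """Emit peaks, coverage tracks, TF peaks, and a lagged expression table.

    Peak read counts are proportional to planted element intensities
    (``reads_per_intensity`` reads per intensity unit); coverage tracks carry
    reads-per-bp values so their integral equals the read count. Genes within
    20 kb of an increasing-trajectory loop anchor rise in expression with a
    one-stage lag relative to the loop-strength ramp. Expression is on the
    log2(TPM/10 + 1) scale.
    """
    rng = np.random.default_rng(seed)
    stages = truth.stages
    n_stages = len(stages)
    peaks, coverage, libsizes = {}, {}, {}
    el = truth.elements
    for mark in MARKS:
        inten = truth.mark_intensity[mark]
        for s, stage in enumerate(stages):
            rows, cov_rows = [], []
            for e in range(len(el)):
                v = inten[e, s] if len(inten) else 0.0
                if v <= 0:
                    continue
                r = el.iloc[e]
                reads = v * reads_per_intensity
                rows.append((r["chrom"], int(r["start"]), int(r["end"]),
                             f"{mark}_{stage}_{e}", reads, "."))
                cov_rows.append((r["chrom"], int(r["start"]), int(r["end"]),
                                 reads / (r["end"] - r["start"])))
            peaks[(stage, mark)] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "name", "score", "strand"])
            coverage[(stage, mark)] = pd.DataFrame(
                cov_rows, columns=["chrom", "start", "end", "value"])
            libsizes[(stage, mark)] = float(peaks[(stage, mark)]["score"].sum()) or 1.0

    tf_peaks = {}
    for s, stage in enumerate(stages):
        occ = truth.tf_occupied[:, s] if len(truth.tf_occupied) else np.array([], bool)
        rows = []
        for e in np.where(occ)[0]:
            r = el.iloc[e]
            rows.append((r["chrom"], int(r["start"]), int(r["end"]),
                         f"TF_{stage}_{e}", 30.0 * reads_per_intensity, "."))
        tf_peaks[stage] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    # expression: lagged response to increasing loops
    genes = genome.genes
    base = np.clip(rng.normal(2.0, 0.8, size=len(genes)), 0.1, None)
    effect = np.zeros((len(genes), n_stages))
    inc = truth.loops[truth.loops["trajectory"] == "increasing"]
    for _, loop in inc.iterrows():
        pos = truth.loops.index.get_loc(loop.name)
        mult = truth.loop_multipliers[pos]
        ramp = (mult - mult[0]) / max(mult.max() - mult[0], 1e-9)
        lagged = np.concatenate([[0.0], ramp[:-1]])  # one-stage lag
        for a in (loop["anchor1"], loop["anchor2"]):
            near = (genes["chrom"] == loop["chrom"]) & \
                   (np.abs(genes["tss"] - (a + LOOP_ANCHOR_BIN // 2)) <=
                    20_000 + LOOP_ANCHOR_BIN // 2)
            effect[near.to_numpy()] = np.maximum(
                effect[near.to_numpy()], loop_expression_effect * lagged)
    stage_mean = base[:, None] + effect

    cells, cell_stages, cols = [], [], []
    for s, stage in enumerate(stages):
        nc = cells_per_stage[s] if s < len(cells_per_stage) else cells_per_stage[-1]
        for c in range(nc):
            cid = f"{stage}_cell{c}"
            vals = np.clip(stage_mean[:, s] + rng.normal(0, expression_noise_sd,
                                                         size=len(genes)), 0, None)
            cells.append(vals)
            cell_stages.append(stage)
            cols.append(cid)
    expression = pd.DataFrame(np.column_stack(cells), index=genes["gene"], columns=cols)
    return SyntheticOmics(
        peaks=peaks, coverage=coverage, tf_peaks=tf_peaks, library_sizes=libsizes,
        expression=expression, cell_stage=pd.Series(cell_stages, index=cols),
    )


def write_synthetic_dataset(
    outdir,
    genome: GenomeModel,
    truth: ArchitectureTruth,
    omics: SyntheticOmics,
    matrices: dict | None = None,
) -> None:
    """Write the generator outputs as plain-text files under ``outdir``."""
    out = hio.ensure_dir(outdir)
    truth.to_json(out / "truth.json")
    (out / "genome.json").write_text(json.dumps(genome.to_dict()))
    genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    for (stage, mark), df in omics.peaks.items():
        hio.write_bed(df, out / f"peaks_{mark}_{stage}.bed")
    for (stage, mark), df in omics.coverage.items():
        hio.write_bedgraph(df, out / f"coverage_{mark}_{stage}.bedgraph")
    for stage, df in omics.tf_peaks.items():
        hio.write_bed(df, out / f"peaks_TF_{stage}.bed")
    expr = omics.expression.copy()
    expr.columns = pd.MultiIndex.from_arrays(
        [omics.cell_stage[expr.columns], expr.columns], names=["stage", "cell"])
    expr.to_csv(out / "expression.tsv", sep="\t")
    if matrices:
        for key, m in matrices.items():
            hio.write_matrix(m, out / f"bins_{key}.tsv", out / f"matrix_{key}.tsv")
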