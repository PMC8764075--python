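# Methods

This document describes the models implemented in `hicdyn`, the default
parameters and their rationale, what the synthetic generator does and does not
emulate, and the numerical choices that make runs reproducible. Every
quantitative claim here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs check.

## Coordinate conventions

All coordinates are 0-based, half-open. A bin of size `b` covers
`[i*b, (i+1)*b)`; a position `p` maps to bin `floor(p/b)`. The last, possibly
partial, bin of a chromosome is kept. The analysis resolutions are 100 kb
(compartments), 40 kb (domains; also the genome grid), 10 kb (loops), and
5 kb (targeted region-pair quantification).

## Contact-matrix core

**Matrices.** Dense, symmetric, non-negative cis matrices per chromosome.
The library size is the upper-triangle sum including the diagonal.

**Knight–Ruiz balancing.** `kr_balance` finds weights `w` such that
`diag(w) C diag(w)` has constant row sums, using the inner–outer Newton
conjugate-gradient iteration of Knight & Ruiz with the standard safeguards
(`delta=0.1`, `Delta=3.0`). Bins with a zero marginal are always excluded
(weight NaN). A configurable low-marginal quantile filter
(`balance.filter_low_count_fraction`, default 0.05) additionally drops the
lowest-coverage bins, as is standard for noisy real data. Convergence
tolerance 1e-6 on the residual, at most 3000 inner iterations; failure raises
`ConvergenceError` rather than returning partial weights. The matrix is
preconditioned by its mean nonzero value for scale stability; weights are
rescaled so balanced row sums are 1.

**Depth normalisation.** `normalize_to_smallest` rescales every library by
`smallest_total / own_total`; the smallest library is returned with scale
factor exactly 1 (bit-identical counts).

**Distance decay and obs/exp.** The expected count at bin separation `d` is
the NaN-aware mean of the `d`-th diagonal. Obs/exp divides each pixel by the
expectation at its separation; zero expectation yields NaN, zero observed at
positive expectation yields 0. Per-diagonal means of the obs/exp matrix are 1
by construction, and the transform is invariant to global rescaling (both are
property-tested).

**Contact-distance profile.** Among pairs at separation > 0 and ≤ 10 Mb, the
short-range fraction counts separations in (0, 2 Mb] and the long-range
fraction (2 Mb, 10 Mb].

## Compartments (100 kb)

A/B calls are the sign of the leading eigenvector of the Pearson correlation
matrix of obs/exp (rows with fewer than two finite values or zero variance are
excluded and reported NA). The eigenvector sign is oriented so that the mean
gene density of A bins is at least that of B bins, the standard resolution of
the eigenvector's sign ambiguity.

**Balancing for the compartment step.** The pipeline balances the 100 kb
matrices with `compartments.filter_low_count_fraction = 0` (only zero-marginal
bins dropped), overriding the 5% default used elsewhere. Reason: a planted (or
real) flip run is a minority-label island whose bins have systematically low
marginals at every stage, so a low-coverage filter preferentially removes
exactly the bins whose flips the analysis is meant to classify — a filter
correlated with the measurement target biases the estimator by construction.
At the default depth (1e6 pairs over 200 coarse bins) every bin is well
covered and the filter serves no purpose.

**Flip taxonomy.** Defined over exactly four stages. A bin NA in any stage is
excluded from the denominator. Stable-A/stable-B if all four labels agree;
A-to-B / B-to-A for a single monotone switch (one change point); transient
otherwise (e.g. B,B,A,B). The flip fraction is the non-stable share of
classified bins.

## Domains (40 kb)

**Insulation.** For each separation stratum the matrix is z-scored
(population SD; zero-SD strata give z = 0), and the insulation score at bin
`b` with window `w` is the mean z over the `w × w` block of contacts crossing
`b` (rows `b-w..b-1`, columns `b+1..b+w`). The first and last `w` bins are
NaN. Boundary strength is the negated score; boundaries are prominence-based
minima (`scipy.signal.find_peaks` on the strength, default prominence 0.1).
Stratum z-scoring makes the score invariant to library depth
(property-tested) and comparable across stages without further normalisation.

**Boundary variability.** Per-bin SD (ddof = 1) of boundary strength across
stages at the union of called boundary bins, adjacent bins merged, ranked by
SD.

**Domain score.** For a TAD `[s, e)`, the raw score is (intra-TAD pair sum) /
(sum of pairs with at least one end in the TAD), computed with prefix sums;
it lies in [0, 1] and equals 1 for a whole chromosome. Normalisation per
library: divide by the mean raw score of `n_sim = 1000` random same-size
placements (placement draws shared across libraries so library differences
are not re-randomised), subtract the library mean (centring is structural —
the normalized scores of each library sum to zero), then quantile-normalise
across libraries (mean-of-sorted reference, tie-averaged). Unenriched TADs on
pure-decay matrices give |mean| < 0.05 (acceptance criterion; measured
≈ 4e-17 because of the structural centring, with individual interior-TAD
values ≈ ±0.03). Chromosome-edge TADs have inflated raw scores (fewer
outside pairs); the random-placement null only partially absorbs this, which
is why calibration checks use interior placements.

**Variable TADs.** One-way ANOVA across stage groups of replicate-level
normalized scores, BH-adjusted, FDR < 0.001, ranked by variance of stage
means. Degenerate features (too few replicates, zero range) are flagged, not
tested.

**Stage-series clustering.** Ward hierarchical clustering of per-row z-scaled
4-stage series; constant rows scale to zero vectors.

## Loops (10 kb)

**Detection.** Candidate pixels lie in the upper triangle with separation in
[50 kb, 2 Mb], have a positive count, a positive donut background, and exceed
`fold_min = 1.5` times the donut mean. The donut is the surrounding
`(2·5+1)²` square with the centre row and column removed (computed by FFT
convolution). Each candidate's count is tested against Poisson(donut mean)
(upper tail), p-values BH-adjusted over candidates, significance at
`p_adj < 0.05`. Significant pixels adjacent in the 8-connected sense merge to
one loop represented by its most enriched pixel. The returned table carries
`attrs["n_band_pixels"]` and `attrs["n_candidates"]` so false-call fractions
can be computed against the actual number of tests.

**Calibration and power.** On 20 loop-free (pure-decay) matrices the
significant fraction of candidates is ≈ 1.6e-05, far below the BH level of
0.05. Power depends strongly on depth: at 2e7 pairs on a 2000-bin matrix,
recall of planted ≥ 4× loops is 1.0; at 1e7 it is 0.8–0.93; at the pipeline
default of 1e6 it is ≈ 0.07 — individual 10 kb pixels simply receive too few
reads. The default depth is a study condition of the synthetic design and is
not tuned upward; the acceptance recall check uses 2e7 pairs ("adequate
depth"), and the end-to-end summary reports the honest shallow-depth recall.

**APA.** Mean obs/exp window (flank 5 bins) over anchor pairs; centre
enrichment is the centre of the mean window divided by the mean of its four
corners. Pairs whose window leaves the matrix are skipped and counted.
Distance-matched random pairs are drawn from the planted separations; the
calibration check uses 400 random pairs (excluding planted pixels) so the
Monte Carlo error of the random-pair centre enrichment is well inside the
1.0 ± 0.1 band.

**CPM.** Loop strength is the raw pixel count × 1e6 / library size.

## Annotation and integration

Promoters are TSS ± 5 kb. Enhancers are H3K27ac peaks that do not touch any
promoter window — a peak overlapping a promoter by even 1 bp is excluded
entirely. Anchor labels use promoter precedence (an anchor overlapping both
is P) so that E-E/E-P/P-P/other is a partition. TF engagement is defined for
E-P loops only: engaged if a TF peak overlaps either anchor, subtyped
promoter-only / enhancer-only / both. Genes are assigned to a loop when their
TSS is within 20 kb of either anchor interval.

ChIP signal over a region is the coverage integral restricted to the mark's
peaks, scaled per million library reads; regions intersecting no peak score
exactly 0. The boundary metaprofile averages this peak-restricted signal in
10 kb offset bins across ± 500 kb windows (101 bins) centred on boundaries,
skipping and counting boundaries whose window leaves the chromosome.

Expression trends classify four-stage means (log2(TPM/10 + 1) scale) with a
dead band of `eps = 0.25` log2 units: all |Δ| ≤ eps → flat; all Δ ≥ 0 with at
least one Δ > eps → up; mirrored for down; anything else → transient.

## Statistics

**Wilcoxon rank-sum.** For pooled sizes ≤ 12 the two-sided p-value is exact:
all C(n, m) assignments of pooled midranks are enumerated, so ties are
handled exactly; p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). The canonical example
x=(1,2,3) vs y=(4,5,6) gives p = 0.1. Larger samples use the normal
approximation with tie correction and continuity correction. Type-I error at
α = 0.05 is calibrated to [0.03, 0.07] over 2000 null simulations (tested).

**BH adjustment** follows the step-up definition (verified against a
brute-force implementation on all permutations of a 6-value set); NaNs pass
through. **Quantile normalisation** maps each column to the mean-of-sorted
reference by average rank, tie-averaged.

## Synthetic generator

The generator is the package's validation instrument: it plants known
multi-scale structure so that every analysis can be scored against truth.

**Genome.** One (default) 20 Mb chromosome, 40 kb bins, 200 genes placed
uniformly at random.

**TADs.** 10 TADs tile the chromosome; edges snap to the 200 kb lattice
(lcm of the 40 kb grid and the 100 kb compartment grid) so compartment
switches can sit exactly on TAD boundaries. TAD trends cycle
stable/increasing/decreasing; intra-TAD enrichment is a base factor
U(1.9, 2.3) times a stage ramp (linspace 0.75→1.25, increasing or decreasing
per trend).

**Compartments.** Blocks are unions of consecutive TADs (each internal TAD
edge ends a block with probability 0.5). Gene-dense blocks are labelled A
until half the bins are A. The segmentation is redrawn (≤ 50 draws, keeping
the best) until the A-vs-B mean gene-density gap is at least 2 SD of the
difference-in-means noise for Poisson gene counts. This emulates the real
coupling between compartment identity and gene density that the eigenvector
orientation rule relies on; with uniformly placed genes an unlucky
segmentation can otherwise make the orientation undefined, which is a
property no real genome has. Planted flips are contiguous runs (geometric
length, mean 3) placed at least 3 compartment bins from TAD edges, with a
single direction or a transient pattern per run.

**Loops.** 30 anchor pairs with separations in [200 kb, 1.5 Mb], anchor bins
on the 10 kb grid. Trajectories follow fixed four-stage multipliers —
increasing (1, 2, 3.5, 5), decreasing (5, 3.5, 2, 1), ephemeral (1, 5, 5, 1),
stable (5, 5, 5, 5) — mixed 0.3/0.3/0.2/0.2 by largest remainder. Anchors are
assigned E/P identities to realise planted E-E/E-P/P-P counts, and a planted
fraction (default 0.409) of E-P loops is TF-engaged. Enhancer anchors require
10.5 kb clearance from every TSS so that a 10 kb enhancer anchor interval can
never graze a promoter window (TSS ± 5 kb): anchor-interval overlap with a
promoter occurs iff a TSS lies within 10 kb of the anchor centre, so 10.5 kb
guarantees noise-free classification is exact.

**Contact matrices.** Expected intensity = (d+1)^(−1) power-law decay ×
compartment concordance (× 1.5 same label, ÷ 1.5 different) × intra-TAD
enrichment × loop multipliers, scaled so the expected upper-triangle total
equals the target depth, then Poisson-sampled. Defaults (depth 1e6, decay
exponent 1.0, concordance 1.5) are study conditions of the synthetic design.

**ChIP and expression.** Each planted element emits a peak with reads
proportional to its stage intensity (10 reads per intensity unit) and a
matching uniform coverage block whose integral equals the read count; library
size is the total peak reads. TF peaks mirror the planted occupancy matrix.
Expression (log2(TPM/10 + 1) scale) draws per-gene baselines N(2.0, 0.8);
genes within 20 kb of an increasing-loop anchor gain up to 2.0 units
following the loop ramp with a one-stage lag; per-cell noise SD 0.4 with
(42, 33, 50, 16) cells across the four stages.

**What the generator emulates:** multi-scale coupling (compartment blocks
aligned to TAD unions), gene-density-biased A identity, stage-coherent flips,
monotone and transient loop trajectories, TF engagement of E-P anchors,
lagged transcriptional response to loop strengthening, and Poisson counting
noise at realistic desk-scale depths.

**What it does not emulate:** trans contacts, multi-chromosome karyotypes by
default, fragment-level biases (GC, mappability) that balancing corrects in
real data (matrices are unbiased before Poisson noise, so KR acts as a no-op
check), replicate batch effects, peak-caller noise (peaks are emitted
directly), copy-number variation, and single-cell dropout structure.

## Determinism and numerics

Every stochastic step derives its seed via `derive_seed(base, *labels)` —
SHA-256 of the label string, reduced mod 2^31 — so sub-streams are
independent and reproducible from one base seed. Summary floats are rounded
to 8 decimals and serialised with sorted keys; two runs with the same seed
produce byte-identical `summary.json` (acceptance criterion 8). Balancing
works on scale-preconditioned matrices; FFT convolution round-off in the
donut background is clipped at zero.

## Limitations

- Loop recall at the default synthetic depth (1e6 pairs) is low (≈ 0.07);
  calling 10 kb loops reliably needs ≥ 1e7 pairs on a 20 Mb chromosome.
  The summary reports the honest value.
- The insulation minimum at a sharp two-block junction is tied between the
  two bins flanking the boundary; calls can land one bin to either side,
  which is why boundary recovery is scored within ± 1 bin. On weakly enriched
  TADs the trough can plateau and shift the called minimum further; with the
  default design this occasionally costs one of nine boundaries in one stage.
- Domain-score normalisation only partially absorbs chromosome-edge effects;
  null-calibration statements apply to interior TADs.
- The exact Wilcoxon path enumerates up to C(12, 6) = 924 subsets; larger
  samples fall back to the tie-corrected normal approximation.
- Compartment calls at 100 kb on a 20 Mb chromosome rest on 200 bins;
  eigenvector orientation needs a nonzero A-vs-B gene-density gap (the
  generator guarantees one; real data generally does too).
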