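# hicdyn

Multi-scale analysis of chromatin-architecture dynamics across a four-stage
developmental trajectory, exercised end to end on a built-in synthetic data
generator.

## Scientific problem

During the endothelial-to-haematopoietic transition, the genome is reorganised
at every scale that Hi-C can see: megabase A/B compartments flip identity,
topologically associating domains (TADs) gain or lose internal connectivity,
and individual enhancer–promoter loops strengthen or dissolve, often with
transcription-factor occupancy at one or both anchors. Quantifying these
changes jointly — rather than one scale at a time — requires a pipeline that
takes raw contact matrices plus ChIP-seq peaks/coverage and expression tables
for four stages and produces comparable, normalised statistics at 100 kb
(compartments), 40 kb (domains), and 10 kb (loops) resolution.

`hicdyn` implements that pipeline:

- **Contact-matrix core** — Knight–Ruiz matrix balancing, sequencing-depth
  normalisation to the smallest library, distance-decay expectation and
  observed/expected transforms, contact-distance profiles.
- **Compartments** — leading-eigenvector A/B calls oriented by gene density,
  and a five-way flip taxonomy over exactly four stages (stable-A, stable-B,
  A-to-B, B-to-A, transient).
- **Domains** — insulation scores, boundary calls, boundary variability,
  intra-TAD domain scores normalised against random same-size placements,
  ANOVA + Benjamini–Hochberg selection of stage-variable TADs, stage-series
  clustering.
- **Loops** — donut-background Poisson loop calling with BH correction,
  loop strength in CPM, aggregate peak analysis (APA), targeted region-pair
  quantification.
- **Annotation** — promoter/enhancer anchor labelling, E-E / E-P / P-P
  classification, TF-engagement subtypes, gene assignment, peak-restricted
  ChIP signals, boundary metaprofiles, four-stage expression-trend classes.
- **Statistics** — exact (enumerated) Wilcoxon rank-sum for small samples,
  BH adjustment, one-way ANOVA, quantile normalisation.
- **Synthetic generator** — plants known compartments, TADs, loops,
  regulatory elements, ChIP tracks, and expression with controlled stage
  dynamics, so every analysis can be validated against ground truth.

## Running the tests

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/
```

The suite includes unit tests with independent brute-force oracles,
property-based tests (hypothesis, derandomised), and an acceptance suite
(`tests/test_acceptance.py`) with one test per acceptance criterion.

## Worked example

Run the full pipeline on the default synthetic configuration (one 20 Mb
chromosome, 10 TADs, 30 loops, 1e6 read pairs per stage and resolution):

```bash
hicdyn run-all --seed 0 --outdir runs/demo
hicdyn report --outdir runs/demo
```

The report digest printed for seed 0:

```
config hash : 756615609935d06a
flip fraction: 0.11 (planted 0.11)
boundary recall per stage: {'HEC': 1.0, 'LT-HSC': 0.88888889, 'eAEC': 1.0, 'pre-HSC': 1.0}
loops per stage: {'HEC': 0, 'LT-HSC': 1, 'eAEC': 0, 'pre-HSC': 1}
E-P engaged fraction (planted anchors): 0.4
```

Selected values from `runs/demo/summary.json` (seed 0):

- Compartment flips: 200 classified 100 kb bins, counts
  `{"stable-A": 158, "stable-B": 20, "A-to-B": 20, "B-to-A": 0, "transient": 2}`,
  estimated flip fraction 0.11 vs 0.11 planted (error 0.0).
- Domains: 26 consensus TADs, 13 stage-variable TADs at FDR < 0.001,
  boundary recall per stage of 1.0 / 1.0 / 1.0 / 0.889.
- Loops: at the default depth of 1e6 pairs, only the strongest loops are
  callable at 10 kb resolution (1 loop in pre-HSC and LT-HSC, APA centre
  enrichment 6.85 and 7.29); planted-loop recall at this shallow depth is
  honest but low (≈ 0.07) — see `docs/methods.md` for the depth analysis.
- Planted-anchor classification (noise-free): class counts
  `{"E-E": 8, "E-P": 15, "P-P": 7}` and TF-engaged fraction 0.4, both exactly
  matching the planted truth.
- Boundary metaprofile (H3K4me3): centre/flank signal ratio 52.5.

Per-step subcommands (`simulate`, `balance`, `compartments`, `domains`,
`loops`, `annotate`) regenerate the synthetic dataset deterministically from
config + seed and run only their own stage.

## Reproduction

All randomness in the package flows from a single seed through
`hicdyn.pipeline.derive_seed` (SHA-256 based, sub-seeds < 2^31); running the
pipeline twice with the same seed produces byte-identical `summary.json`
files. To reproduce the acceptance quantities:

```bash
python scripts/acceptance.py --seed 1 --out acceptance.json
```

This runs the main computations (oracle deviations, KR balancing quality,
boundary recovery, flip recovery, domain-score null calibration and
monotonicity, loop calibration/recall/APA, classification exactness, and the
end-to-end determinism check) and writes each quantity as
`{"value": <number>, "n": <size>}`. With `--seed 1` the headline values are:
flip-fraction error 0.0 (n=200), minimum boundary recall 1.0 (n=36),
domain-score null |mean| 4.2e-17, increasing-TAD Spearman ρ = 1.0, loop null
significant fraction 1.6e-05 (n=315,980 candidates), planted-loop recall 1.0
at 2e7 pairs, APA centre enrichment 3.03 planted vs 0.98 random, and planted
E-P engaged fraction 0.4 recovered exactly.

## Layout

```
src/hicdyn/        package modules (contacts, compartments, domains, loops,
                   annotate, stats, synthetic, config, io, pipeline, cli)
tests/             unit, property, and acceptance tests
scripts/           acceptance.py report generator
docs/methods.md    models, parameter defaults, and limitations
```
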