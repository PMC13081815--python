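# Methods

This note documents the models, estimators and design choices behind
`adaptscales`, what the synthetic generators do and do not emulate, and the
numerical conventions that make results reproducible.

## Preprocessing

Cells are retained when they express between `min_genes` (200) and
`max_genes` (4,000) genes — "expressed" meaning a strictly positive UMI
count — and carry at least `min_counts` (300) total UMIs; all bounds are
inclusive. Genes expressed in fewer than `min_cells_per_gene` (10) of the
retained cells are then dropped. Cell filters run first and the gene filter
is computed on the cell-filtered, pooled dataset (a per-sample variant is
available via flag); the applied order and removal counts are recorded in a
filter report so the provenance of any matrix is auditable. Normalization
rescales each cell to `target_sum` (10,000) total counts and applies the
natural `log1p`; consequently `exp(values) − 1` row-sums to the target for
every cell, a property the tests verify as a round trip. No doublet
removal, ambient correction, HVG subsetting or batch integration is
performed — the downstream decomposition operates on the full
log-normalized, unscaled matrix.

## Eigenspectrum

The decomposition is a truncated SVD of the per-gene mean-centered matrix
(centering makes the components principal components and gives "variance
explained" its usual meaning; a flag disables it). Matrices whose smaller
dimension is ≤ 600 use dense LAPACK SVD — the reference path — and larger
ones a seeded randomized solver that the tests require to agree with the
dense path on spectra with realistic decay. Two conventions matter for
reproducibility:

* **Sign fixing.** Each component is flipped so its largest-|loading| gene
  is positive (ties resolve to the first such gene), making `U`, `V`
  reproducible across runs, platforms and solvers.
* **Exact total variance.** Variance fractions divide by the squared
  Frobenius norm of the full centered matrix, computed directly from the
  data, so fractions remain correct when only `K ≪ rank` components are
  retained.

`spectrum_linearity` fits ordinary least squares of variance fraction
against rank over a component window; an exactly constant spectrum is
reported as degenerate with `r² = 0` rather than undefined.

## SCALES: spectral MI profiling

Left singular vectors are scanned with sliding windows of 3 consecutive
components, stride 1, covering components 1–30 by default (all three are
configurable). For each sampled unordered cell pair, the window's spectral
correlation is the inner product of the two cells' projections; projections
are singular-value-weighted (`U·diag(s)`) by default because a cell's
coordinates in expression space carry the scale of each component — an
unweighted variant is available, as is cosine normalization. One pair
sample is drawn once per analysis (uniform without replacement, exhaustive
when the total pair count fits the budget, default budget 2×10⁶) and reused
across every window, variable and permutation, so all curves within a run
share their sampling noise.

MI between the correlation values and the binary same-label indicator uses
equal-frequency discretization into at most 16 bins (ties share a bin) and
the plug-in estimator in bits. The estimator is deliberately simple: it is
exactly the double sum over the joint histogram, which the tests verify
against an independent brute-force evaluation to 10⁻¹² bits, and it handles
multi-level variables through the same/different pair indicator without
one-vs-rest expansion. Plug-in MI on ~10⁵ pairs has an upward bias of order
`(bins−1)/(2 N ln 2)` ≈ 10⁻⁴ bits; because every window shares `N` and the
binning scheme, the bias cancels in within-run comparisons, and the
permutation null absorbs it entirely.

The cumulative MI(CDF) curve is the running sum of per-window MI, reported
raw and normalized to its final value. **Spectral depth** is the first
window where the normalized curve reaches 0.5 (threshold configurable);
variables sorted by depth, with ties broken by larger total MI and then by
name, form the hierarchy. The half-rise statistic is this package's
operationalization of "where the curve rises": it is the minimal monotone
summary of the curve, and its behaviour under leakage (below) is why the
null envelope is always reported next to it.

### Permutation null

The default `per_condition` null permutes the assignment of the variable's
values across whole sample blocks, preserving within-sample transcriptional
structure; a `per_cell` mode shuffles labels across cells. The envelope
reports per-window mean and 95th percentile of the null MI, plus the null
maximum — the upper edge of the band spanned by all null curves. Two
different uses follow: *signal* claims compare a window's MI against the
null 95th percentile; *absence-of-signal* claims (calibration of a
zero-effect dataset) check containment within the spanned envelope, whose
per-window exceedance probability is `1/(n_perm+1)` rather than the
nominal 5% of a quantile — a containment test at the 95th percentile would
fail ~5% of windows by construction even on pure noise.

Block structure itself leaks a little MI into every window: pairs drawn
from the same condition are enriched among same-label pairs and have
distinctive correlations wherever condition-level structure exists. The
per-condition null reproduces exactly this enrichment, which is why it —
and not the per-cell shuffle — is the default reference for profiles of
condition-constant variables.

## Dual-stress epistasis

Bulk counts are normalized to CPM with a pseudocount of 1 and log2
transformed; replicates are averaged in log space (median-of-ratios size
factors were considered and rejected as unnecessary for a 2×2 design read
out through medians, but the normalization used is recorded in output
metadata). The independence expectation for the dual stress is additive in
log2 — multiplicative on the linear scale — and the per-gene deviation
`lfc_dual − lfc_heat − lfc_osmo` is summarized per gene set by its median,
alongside a transcriptome-wide row. The per-gene deviation of a typical
gene is noise-dominated at realistic sequencing depth (three replicates of
a ~10⁶-read library put ~0.1–0.2 log2 units of noise on a single gene's
deviation); the calibrated, reported statistic is therefore the set
median, whose bias under simulated independence the acceptance suite bounds
at 0.05 log2 units. Condition correlations are Pearson on the filtered
log2 matrix; strain concordance is squared Pearson over the gene
intersection, on the log scale.

## Physiology

**Polysome quantification.** Traces are smoothed with a 5-point moving
average; the 80S monosome is the tallest local maximum in the first half of
the trace (past the 40S/60S shoulders it dominates), bounded by flanking
local minima, with everything from the following minimum to the trace end
assigned to polysomes. Manual bounds are authoritative and bypass
detection; traces whose dynamic range falls below 0.05 absorbance units are
rejected as flat/noise-only rather than quantified. Integration is
trapezoidal on `A260 − baseline` clipped at zero; the default baseline is
the straight line between the region's endpoint absorbances (robust to
gradient drift), with constant-minimum and zero baselines available. With
well-separated peaks this recovers planted area ratios to well under 2%;
strongly overlapping shoulders (40S/60S tails under the 80S) bias areas at
the few-percent level, which is why published P/M values from real traces
should be treated as orderings rather than absolutes.

**Growth rates.** ln OD600 is scanned with 5-point sliding windows
(~100 minutes at 20-minute sampling) after a 5-point moving average of the
OD series; the maximum OLS slope over windows whose ODs lie within
`[od_min, od_max]` is the rate. The pre-smoothing matters: the maximum of
many short-window slopes on unsmoothed data is strongly upward-biased at
low OD, where relative noise is largest. A fixed-band preset
(`od_min=0.4, od_max=0.5`) reproduces turbidostat cycle-rate estimation.
Note that on a logistic curve the instantaneous log-slope never quite
reaches the nominal rate parameter; the estimator is accurate in the mean
(within 5% across seeds at noise sd 0.01) while individual noisy curves
scatter more widely.

**Diauxie.** The smoothed instantaneous-rate series (window slopes over
ODs above a 0.04 floor) is searched for two maxima above 0.05/h, at least
2 h apart, separated by a trough below half the first maximum. This
criterion is an operational definition — the underlying phenotype is
reported in the literature without a formal rule — and pipeline output
flags it as such. The synthetic diauxic model is two exponential phases
capped at their capacities with an idle lag between, so each phase's
specific rate is a directly observable log-slope.

**Competitive fitness.** The selection coefficient is the OLS slope of
`ln(count_test/count_reference)` against day. Daily dilution affects both
strains equally and cancels in the ratio, so no correction is applied; a
zero count violates the series' invariants and is an error rather than a
silently dropped point. At 10⁴ cytometry events per day the binomial
standard error of the slope is ≈0.01/day, so single-assay estimates of
s = 0.1/day carry ~10% noise; the acceptance suite accordingly tests the
mean over 20 simulated assays.

## Synthetic ensemble generator

The single-cell generator plants each cue at a chosen component of the
condition-level expression structure:

* Orthonormal gene programs `q_1..q_K` come from QR of a seeded Gaussian
  matrix (sign-fixed).
* The per-condition natural-log mean is
  `baseline + √n_genes · Σ_k coeff_k(condition) · q_k`. The coefficient of
  a cue's planted component is its centered, unit-variance level code times
  the cue's effect size; every other component carries a background
  condition program whose amplitude interpolates the planted
  (depth, effect) anchors, so the amplitude ladder decreases smoothly and
  planted depths are literal ranks, not just an ordering.
* Effect sizes are relative; multiplied by `effect_gene_scale` (0.35
  ln-units) they give RMS per-gene log fold shifts, making the strongest
  cue a ~1.4-fold RMS transcriptome-wide perturbation and keeping per-cell
  expression breadth realistic (~400–600 detected genes of 1,000 at ~2,000
  UMIs). Counts are negative-binomial (inverse-dispersion 10) around
  softmax means scaled by log-normal library sizes.

Two constructions keep the planted structure identifiable, both found
necessary during design:

1. **Background programs are balanced ±1 condition codes, orthogonalized
   against every cue code and each other.** Orthogonality prevents
   background components from carrying cue information (Gaussian or
   interaction-contrast backgrounds leak label information through
   correlation and through magnitude coupling with cue components inside a
   shared window); the near-two-valued distribution matches the cue codes,
   so the concave count-compression of normalization attenuates planted
   and background components alike and the realized variance ladder tracks
   the planted amplitudes to a few percent.
2. **The shared stress shift** — applied along the leading background
   program to every non-reference condition — is orthogonalized against the
   cue codes, since on a near-full factorial the raw any-stress indicator
   correlates ~0.15 with every cue and would rival the deepest cue's own
   effect.

What the generator does **not** emulate: cell-cycle and cell-to-cell state
variation beyond count noise, gene–gene correlation outside the planted
programs, ambient RNA, doublets, batch effects, and the heavy-tailed
per-gene dispersion of real UMI data. Recovery of the planted hierarchy
therefore demonstrates that the estimator chain is correct and calibrated
under its own assumptions, not that any particular real dataset will
resolve its cues as cleanly.

The bulk generator draws disjoint heat- and salt-responsive gene sets whose
linear-scale mass is exactly conserved under their stress (induced and
repressed genes balance). This mirrors the approximate compositional
neutrality of real global stress responses and makes CPM normalization
exact rather than a confounder: in the noiseless limit with no planted
interaction, deviations are identically zero, giving the pipeline a sharp
correctness oracle.

## Problem sizes and determinism

All generators are bit-reproducible from their seed (integer counts
identical across runs). Analyses of the default ensemble (48 conditions ×
100 cells × 1,000 genes) in the test and acceptance suites use a pair
budget of 150,000 with 100 permutations — at these sizes the MI noise floor
(~10⁻⁴ bits) sits two orders of magnitude below the weakest planted signal,
and a full 20-seed hierarchy-recovery experiment completes in minutes on
one CPU. The pipeline writes TSV/JSON with fixed numeric formatting, and a
rerun with the same config and seed is byte-identical; the manifest (which
carries wall-clock time) is the only output excluded from that guarantee.

## Known limitations

* Plug-in MI with quantile binning is the only estimator (the interface
  admits alternatives); continuous metadata variables are out of scope.
* Spectral depth depends on the analyzed depth (PCs 1–30) and the 0.5
  threshold; variables encoded mostly beyond the last window are flagged
  undefined rather than extrapolated.
* Automatic polysome region detection assumes a dominant 80S peak in the
  first half of the trace; unusual gradients need manual bounds.
* The epistasis module quantifies levels and medians; it performs no
  differential-expression inference and no multiple-testing machinery.
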