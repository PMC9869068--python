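# Methods

This note documents the models, conventions, and numerical choices behind
`restfc`, and what the synthetic generator does and does not emulate.

## Data model

A subject is a T × N matrix of BOLD values (rows = timepoints, columns =
ROIs) with an ROI-label header, a repetition time TR (seconds), and a
subject id. Edge indexing is positional: entry (i, j) of every edge-level
matrix refers to columns i and j of the time-series files, so ROI column
order must be identical across a cohort and is validated before statistics
run (a permuted header is an error, not a reorderable difference). The TR is
supplied by configuration, not stored in the data files, which stay plain
inspectable TSV matrices.

## Static functional connectivity

FC is the Pearson correlation between the full time series of each ROI pair,
giving a symmetric N × N matrix with unit diagonal per subject. The global
mean FC is the mean of the strict upper triangle. Group summaries are
entrywise means and sample SDs (denominator n − 1; every SD in the package
uses the sample convention so the z-score, MAD, and ANOVA scales agree).

Edges that reach significance are additionally screened for outliers within
each group: a subject is flagged when its FC at that edge is more than
3 × 1.4826 × MAD from the group median (1.4826 is the normal-consistency
constant; the degenerate MAD = 0 case flags any value off the median and
logs a warning). The screen is edge-wise, not whole-subject: a subject is
excluded only at the edges where it is an outlier. Statistics are re-run on
the trimmed groups and both pre- and post-removal results are reported side
by side for auditability.

## Sliding-window variability

Windows are half-open index ranges [s, s + w) with start step 1 (maximally
overlapping; trailing partial windows are dropped). FC is computed
independently inside each window with the same estimator as the static FC,
and the across-window sample SD per edge is the variability map. Defaults:
w = 30 timepoints (90 s at TR = 3 s), the value the window-length assessment
supports. No tapering or weighting is applied.

The assessment sweeps w from 5 to T (step 1), recording the mean FC over all
edges and windows and the mean across-window SD over edges, plus their
differences from the full-record values. At w = T there is exactly one
window, so the FC difference is exactly zero and the SD is zero by
convention. Entries identical across all windows are reported as exactly
zero spread (the floating-point mean otherwise leaves ~1e−17 residue).

## Point-process analysis

Events are defined on z-scored series (each column to mean 0, sample SD 1),
so the 1σ threshold is exactly 1.0; inputs whose column SD deviates from 1
by more than 1e−6 are rejected with a pointer to the z-score step. The
threshold is strict (z > 1, not ≥): on continuous data the difference has
measure zero, but the convention is fixed for reproducibility.

Two event modes exist. `point` (the default) marks every suprathreshold
sample — this is the mode the co-activation "matrix of addition" uses, since
it sums all relevant timepoints. `upcrossing` marks only entries into the
suprathreshold state, the convention of level-crossing statistics (a series
starting above threshold counts at t = 0 in the raster, but the plain
crossing counter counts transitions only, matching the analytic crossing
formulas). The co-activation matrix is counts(i, j) = Σ_t e_i(t) e_j(t) with
per-ROI totals on the diagonal; counts are raw (not normalized by total
events), consistent with reported group mean counts in the 3–11 range for
140-volume scans. Group comparison uses the raw counts.

## Graph metrics

FC matrices are binarized at a signed threshold: edge iff r > threshold
(strict; absolute values are deliberately not used, so strong negative
correlations never become edges). Default threshold r = 0.3 with a sweep
over 0.1–0.5 in steps of 0.01 (41 thresholds).

- Degree: row sum; mean over nodes.
- Clustering: C_i = 2 · (edges among neighbours) / (k_i (k_i − 1)), with
  C_i = 0 for nodes of degree < 2 (the standard binary-toolbox convention).
- Characteristic path length: mean unweighted shortest-path length over
  ordered pairs i ≠ j with finite distance. Disconnected pairs are excluded
  from the mean and their fraction is reported alongside; at the default
  threshold realistic FC graphs are near-complete, so the choice is
  low-impact. Global efficiency (mean inverse distance, defined on
  fragmented graphs) is provided as the harmonic alternative.
- Scale-freeness diagnostic: R² of a straight-line fit to the log–log degree
  survival function. This is a screening heuristic supporting
  threshold-selection arguments, not a formal power-law test; regular
  degree distributions return NaN.

Implementation is numpy + scipy.sparse.csgraph; the test suite checks all
metrics against networkx on random graphs to 1e−10.

## Group statistics

Per edge (or per scalar measure) the model is the classical fixed-effects
one-way ANOVA: F = MS_between / MS_within with df (G − 1, n − G), p from the
F distribution. Cells with zero within-group variance and unequal means are
degenerate; they are reported with p = 0 and a flag rather than dropped.
The edge-wise screen is fully vectorized across the upper triangle.

Post-hoc comparisons use pooled-variance t statistics,
t = (x̄_a − x̄_b) / √(MSW (1/n_a + 1/n_b)) on the ANOVA's within df, with
raw p multiplied by the Bonferroni factor G(G − 1)/2 and clamped at 1.
Tukey-type studentized-range comparisons are not implemented.

The Bonferroni family is configurable because the family a study corrects
over is a genuine modelling choice: `posthoc_only` (default) corrects only
the pairwise family inside each screened edge — per-edge p-values in the
10⁻³–10⁻⁴ range over thousands of edges cannot have survived an edge-family
correction, so this matches how such tables are produced in practice;
`edges_bonferroni` corrects the screen over all edges; `both` applies both;
`none` applies neither. Results tables record the raw p, the screen p after
the configured correction, and the adjusted post-hoc p.

## Synthetic cohort generator

The generator stands in for access-gated clinical rsfMRI data. It emulates
the printed acquisition conditions — 116 ROIs, 140 timepoints at TR = 3 s
(420 s) per subject, four groups of 35/29/30/34 subjects — and the one
spectral ground truth available for BOLD at this TR: an empirical 1σ upward
crossing rate of 8.5 ± 2.8 per 4-minute scan.

Model: per subject, T i.i.d. multivariate-normal timepoint vectors with a
block-structured correlation matrix (default 8 equal blocks, r = 0.5 within,
0.25 between, a crude large-scale-network model whose global FC level puts
the default binarization threshold inside the degree distribution's dynamic
range). Group effects are planted by overwriting chosen edges with target
correlations; the matrix is then repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping at 0 and diagonal
renormalization, with the Frobenius repair distance logged so planted
effects can be audited post-repair.

Temporal structure is imposed by an ideal (brick-wall) zero-phase FFT
band-pass, default flat 0.01–0.05 Hz, applied identically to every column,
followed by a deterministic rescale by the filter gain so each column has
unit population variance. Because filter and rescale are one common linear
operation, the output is exactly Gaussian with exactly the requested
instantaneous cross-correlation — planted edge values are recovered in
expectation by the sample correlation. The default band is narrower than
the usual 0.001–0.1 Hz preprocessing band: a flat band that wide implies a
1σ crossing rate near twice the empirical BOLD figure, while the flat
0.01–0.05 Hz band's analytic rate (≈ 8.3 per scan) sits inside 8.5 ± 2.8.
The band is configurable. A sampled flat band at T = 140 retains 17 Fourier
bins (34 real degrees of freedom), which also reproduces realistic
per-subject FC sampling noise (SE(r) ≈ 0.17 at r = 0, matching reported
group SDs of 0.2–0.3).

Per-subject seeds are spawned deterministically from the master seed
(`numpy` SeedSequence), so a cohort is a pure function of (config, block
spec, effects).

Deliberately not modelled: hemodynamic response convolution, motion and
physiological artifacts, scanner drift, spatial structure within ROIs,
non-Gaussian amplitude features, and non-stationarity. Consequently,
passing tests demonstrate the pipeline's correctness and calibration on
stationary Gaussian band-limited data — not robustness to realistic
artifacts, and dynamic-FC variability here reflects sampling variability
only, not genuine state switching.

## Crossing-rate predictions

Three analytic forms are exposed for the flat band:

1. Continuous Rice rate: ν(u) = √(λ₂/λ₀)/(2π) · exp(−u²/2) with the flat
   band's spectral moments; ≈ 8.19 crossings per 420 s at u = 1σ.
2. Discrete pair formula: E[count] = (T − 1) · P(X_t ≤ u, X_{t+1} > u)
   under a bivariate normal with the band's lag-1 autocorrelation
   ρ = mean over retained bins of cos(2π f TR); ≈ 8.17.
3. Self-normalized exact form (the default): measured series are z-scored
   by their own sample SD, which shifts the effective threshold. For a flat
   band the covariance of the sampled series is a scaled orthogonal
   projection onto the 2K retained Fourier modes, so the z-scored series is
   uniform on a sphere and independent of its sample variance; the crossing
   probability becomes an exact bivariate-normal × chi-square mixture
   evaluated by 2-D quadrature; ≈ 8.33, matching simulation within
   Monte-Carlo error. This form assumes the flat (equal-eigenvalue) band
   and no DC/Nyquist bin in the passband.

## Problem sizes used in the validation suite

Oracle checks run on 100 random instances each (10–24 timepoints, 4–6 ROIs;
30-node random graphs). Statistical calibration uses identity-covariance
null cohorts of 4 × 20 subjects × 30 ROIs: the per-edge type-I error is
pooled over 10 cohorts and checked against 99% binomial bounds around
α = 0.05, and the Bonferroni family-wise error and global-mean ANOVAs are
checked over 60 cohorts with one-sided binomial slack. Effect recovery
plants the flagship effect (edge FC 0.38 in AD vs 0.13 in EMCI, baseline
0.25) in 100 replicate 20-ROI cohorts of 30 subjects per group and requires
the planted edge to top the screen with the correct direction in ≥ 90. The
crossing-rate check averages 1,000 series. These sizes keep the full suite
around half a minute on one core while leaving the binomial bounds tight
enough to detect real miscalibration.

## Known limitations

- The PSD repair can shift planted edge values slightly when targets
  conflict with the block baseline; the repair distance is logged, and
  recovered group means should be read from the generator's output, not
  assumed equal to the targets.
- Characteristic path length on heavily thresholded (fragmented) graphs
  depends on the finite-pair convention; compare like with like, or use
  global efficiency.
- The edge-wise screen assumes homoscedastic Gaussian edge values within
  groups (classical ANOVA); count-valued co-activation data are treated on
  the same footing, which is adequate at these counts but approximate.
- `upcrossing` events at t = 0 are a boundary convention (raster counts a
  start-above sample; the crossing counter does not).
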