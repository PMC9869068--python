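# restfc

Resting-state fMRI functional-connectivity analysis for ROI-level BOLD time
series, built for group comparisons across clinical cohorts (e.g. healthy
controls vs. early/late mild cognitive impairment vs. Alzheimer's disease).
It implements four complementary views of the same data and the statistics to
compare them across groups:

- **Static FC** — Pearson correlation r(i, j) between the full time series of
  every ROI pair, with a 3-scaled-MAD outlier screen
  (MAD × 1.4826, the robust SD estimate) on significant edges.
- **Sliding-window variability (SWA)** — FC inside overlapping windows
  (default 30 timepoints = 90 s at TR = 3 s, step 1) and the across-window
  standard deviation per edge, plus a window-length assessment curve
  (w = 5 … T) exposing the sensitivity/robustness trade-off.
- **Point-process analysis (PPA)** — reduction of each z-scored series to the
  timepoints exceeding 1σ and the "matrix of addition": per edge, the count
  of timepoints where both ROIs are simultaneously suprathreshold.
- **Graph metrics** — binarization of FC at a signed threshold (default
  r > 0.3, no absolute values), then characteristic path length L, mean
  clustering coefficient C, and mean degree k̄, with a 0.1–0.5 threshold
  sweep and a heavy-tail (scale-freeness) diagnostic.

Group differences are tested edge-wise (and measure-wise) with a one-way
ANOVA, F = MS_between / MS_within, followed by pooled-variance pairwise t
comparisons Bonferroni-corrected over the G(G−1)/2 pairs at p < 0.05; the
correction family is configurable.

Because real clinical rsfMRI data are access-gated, the package ships a
**synthetic cohort generator**: band-limited Gaussian BOLD surrogates
(flat 0.01–0.05 Hz passband, 140 timepoints, TR = 3 s) with block-structured
inter-ROI correlation and planted group-specific edge effects. The flat band
is analytically tractable — the generator's 1σ upward-crossing rate has an
exact Rice-type prediction (~8.3 per 420 s scan) matching the empirical BOLD
figure of 8.5 ± 2.8 crossings per 4 minutes.

## Worked example

```python
import restfc

# a 4-group cohort with one planted edge difference (AD 0.38 vs EMCI 0.13)
config = restfc.GeneratorConfig(
    n_per_group={"HC": 20, "EMCI": 20, "LMCI": 20, "AD": 20},
    n_rois=20, seed=42,
)
spec = restfc.default_block_spec(20, n_blocks=4)
effects = restfc.default_planted_effects(edge=(0, 10))
manifest, cohort = restfc.simulate_cohort(config, spec, effects)

fc = {sid: restfc.pearson_fc(ts) for sid, ts in cohort.items()}
table = restfc.edgewise_screen(fc, manifest)
top = table.iloc[0]
print(f"top edge ({top.roi_i}, {top.roi_j}): F = {top.F:.1f}, p = {top.p:.2e}")
print(f"AD mean r = {top.mean_AD:.3f}, EMCI mean r = {top.mean_EMCI:.3f}")
```

prints

```
top edge (0, 10): F = 7.2, p = 2.57e-04
AD mean r = 0.351, EMCI mean r = 0.104
```

i.e. the screen ranks the planted edge first and recovers the two planted
group means (targets 0.38 / 0.13) to within sampling error of 20 subjects. The `restfc` console
script exposes the same stages from a shell
(`restfc simulate | fc | swa | ppa | graph | stats | run`); `restfc run`
drives the whole pipeline from an INI config and writes every result table
into a reproducible output directory.

sklearn users can compose the estimator layer directly:
`PearsonConnectivity`, `SlidingWindowVariability`,
`PointProcessCoactivation`, `GraphMetricsExtractor` (transformers) and
`EdgewiseAnovaScreen` (a fit-style screen) work inside sklearn pipelines.

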