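# Methods

This note documents the models, estimators and numerical choices behind
`modcortex`, and what the synthetic-data tests do and do not establish about
real recordings.

## The analysis model

Spontaneous activity in the developing cortex is treated as a sequence of
discrete events. Each event contributes one spatial pattern (its *event
frame*, the maximally active frame), and the ensemble of N patterns is the
object all second-order statistics are computed on: seed-point correlation
fields, their distance profiles and surrogate nulls, radial-autocorrelation
wavelength and modularity, and the cross-validated variance spectrum. The
pipeline therefore makes two structural assumptions: that events are
temporally separable at the acquisition rate (15 Hz widefield, 30 Hz
2-photon), and that a single frame per event is an adequate summary of its
spatial pattern. Both mirror the standard practice for this preparation.

## Stage parameters

| Stage | Parameter | Default | Notes |
|---|---|---|---|
| ΔF/F | median window | 15 s | valid range 10–23 s, chosen per session |
| ΔF/F | `baseline_stride` | 1 | > 1 evaluates the median on a frame subgrid and interpolates; the baseline varies over tens of seconds, so strides ≤ ~2 s are statistically equivalent and much faster |
| events | pixel threshold | mean + 3 SD | per-pixel statistics over all frames |
| events | min region | 0.01 mm² | 8-connected components |
| events | active fraction | > 40% | of ROI pixels |
| patterns | band-pass | s_low 33 µm, s_high 195 µm | Gaussian SDs; s_low mid-range of 26–41 µm |
| patterns | analysis grid | 160 × 135 | ~19 µm/pixel after 4× block averaging of a 640 × 540 camera frame |
| corrnet | maxima separation | 800 µm | greedy suppression in descending r |
| corrnet | long-range band | 1.8–2.2 mm | from the seed point |
| corrnet | surrogates | 100 | rotations in 10° steps, reflections p = 0.5 per axis |
| corrnet | seed grid stride | 4 px | configurable; statistics are stable in the stride because maxima are pooled over seeds |
| modularity | control sets | 100 | event-count-matched draws from the bottom activity decile of non-event frames |
| dimensionality | splits | 20 | averaged split-half cross-validation |
| cellular | α | 0.4 | neuropil weight |
| cellular | cell threshold / frame fraction | 2 SD / > 5% | population event detection |
| cellular | subsampling | 50 cells × 100 frames × 100 samples | size-controlled dimensionality |
| cellular | LCI annuli | 50-µm rings, 30–600 µm | excluding pairs with |r| < 0.01 |

## Estimators

**Seed correlations.** Patterns are z-scored per pixel across the ensemble
(population SD, 1/N); the correlation field for a seed is the mean product
of z-scores. This is algebraically the Pearson correlation and is verified
against a per-pixel `corrcoef` loop to 1e-12.

**Surrogate null.** Each pattern of each surrogate is independently rotated
about the ROI centroid by a uniform multiple of 10° and reflected across
each axis with probability 0.5 (bilinear interpolation; trig values at
multiples of 90° are snapped so axis-aligned rotations are exact). Pixels
whose source falls outside the ROI are *undefined*, never filled: a
surrogate's correlation statistics use only pixels valid in all of its
patterns. This destroys inter-pattern spatial relationships while
preserving single-pattern statistics. Note that the surrogate median
correlation *at maxima* is positive (~+2/√N) by selection — maxima are the
upper extremes of a smooth null field — so significance must compare
like-for-like statistics, as done here.

**Wavelength and modularity.** The 2-D autocovariance is computed by
zero-padded FFT and divided lag-by-lag by the mask overlap count, so an
irregular ROI does not bias it, then normalized at zero lag and averaged in
one-pixel annuli. Λ = 2 r_min at the first strict interior minimum, with
parabolic sub-bin refinement — except for extrema adjacent to zero lag,
where the lag-0 noise-variance cusp would make the parabola overshoot.
Band-pass-filtered noise acquires a spatial scale and hence nonzero
modularity; this is why the null uses low-activity *control frames* passed
through the identical filter, not white noise.

**Dimensionality.** Patterns are mean-centered per pixel, split in half;
axes come from the training half's SVD and λ_i is the variance of the test
half's projections. Negative cross-validated variances are clipped at zero
before the participation ratio (conservative; the ratio is ill-behaved for
negative terms). The reported d_eff averages 20 seeded splits.

**Module amplitude.** Peaks are local maxima of the Λ/8-smoothed unfiltered
event frame above median + 2·MAD (the adaptive criterion is this package's
own, explicit and testable); each peak's amplitude is its raw ΔF/F divided
by the median ΔF/F on the one-pixel ring Λ/2 away, averaged over peaks.

## The synthetic generator

Modular patterns are Gaussian random fields with an annular power spectrum
at k0 = 2π/Λ_F (relative width 0.15). The annulus is chosen because its
autocorrelation has the closed form J0(k0 r): the first minimum sits at
r = 0.6098 Λ_F and the first zero at r = 0.383 Λ_F, giving analytic oracles
for the wavelength estimator (expected estimate 1.22 Λ_F) and the LCI zero
crossing.

Event patterns are half-wave-rectified Gaussian mixtures of n_basis
orthogonalized fields, rectified about a positive activation offset
(default 2 mixture-SD units). The offset models the observation that
inter-module cortex during an event is elevated rather than silent (module
peak/background ratios around 3); it simultaneously keeps rectification a
mild tail nonlinearity, so the ensemble covariance — and therefore the
recoverable dimensionality — remains that of the planted n_basis mixture,
and it makes the > 40%-active-fraction detection rule attainable, which a
zero-mean rectified field can never satisfy at a 3 SD pixel threshold.

Movies place events on a regular schedule with within-slot jitter at
0.02 Hz (one event per ~50 s, the sparse-event regime of this immature
preparation under anesthesia); each event's profile is scaled so a typical
module flank reaches peak ΔF/F = 0.5 (10× the 0.05 sensor-noise SD) and
convolved with a difference-of-exponentials indicator kernel (rise 0.2 s,
decay 2 s, GCaMP6s-like). The baseline carries a slow ±3% multiplicative
drift. Cellular traces sample the field bilinearly at random positions,
add cell noise and a neuropil term (the 20-µm local field average, weight
0.3); a salt-and-pepper control permutes cell positions while keeping every
trace.

What the generator does *not* emulate: hemodynamic and motion artifacts,
event-to-event amplitude heterogeneity, spiking statistics, multi-area
geometry, or irregular ROIs. Passing tests therefore establish the
correctness and calibration of the estimators under the stated statistical
model, not robustness to every artifact of real data.

## Numerical and design choices

- Grid coordinates are 0-based (row, col); physical positions are at pixel
  centers; distances are internal µm, reported as mm (widefield) or µm
  (cellular).
- Registration is integer-pixel only; downstream statistics are robust to
  sub-pixel error at 19 µm pitch.
- Running medians use reflect padding; strided evaluation interpolates
  linearly between sampled medians and subsamples within the window (≤ 45
  frames), both exact in the limit of slow baselines.
- Event runs are split at *strict* interior local minima (ties resolve
  toward the earlier frame); boundary events are kept and flagged.
- p-values from n-sample nulls are counting fractions with resolution
  floor 1/n (a zero count is reported as "< 1/n").
- Per-frame z-scoring of cellular event frames induces a −1/(n_cells − 1)
  correlation among cells; against the within-cell shuffle null this biases
  p conservatively (toward 1) for structureless data, never toward false
  positives.
- The end-to-end driver derives per-stage seeds from one global seed by
  stage-name hashing, making runs byte-reproducible while keeping stages
  statistically independent.
- Degenerate inputs: constant patterns, zero-variance seeds and pixels,
  all-zero spectra, empty ROIs and empty event sets raise or flag rather
  than propagate NaNs silently; monotonic radial profiles are flagged
  `no-minimum-found` and excluded from medians with a QC count.

## Problem sizes

The test suite and the reproduction script run on reduced but structurally
faithful problems: 1.6–3.0 mm fields of view, 20–100 events (400 for
dimensionality recovery), 100 surrogates and control sets, 150 cells.
These sizes keep a full run to a few minutes on one core while leaving
every statistic well-resolved; all are parameters, and scale directly to
full-session recordings.

## Known limitations

- Kruskal–Wallis group comparison is provided as a thin wrapper; post hoc
  pairwise tests (Conover–Iman with Holm correction) are delegated to
  dedicated statistics packages.
- The peak finder behind module amplitude is an explicit substitute for the
  unparameterized external routine used historically in this field; its
  threshold (median + 2 MAD) is exposed.
- Whether surrogate transforms are applied before or after band-pass
  filtering is not canonical; the pipeline transforms filtered patterns.
  Transforming raw frames instead amounts to building the surrogate
  ensemble from an unfiltered `PatternEnsemble`, which the API permits.
- The temporal autocorrelation defaults to the ROI-mean trace; a per-pixel
  average is available by flag.
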