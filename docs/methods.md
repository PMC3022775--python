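# Methods

## The assay and what the pipeline measures

Copper sulfate added to the water kills hair cells in the zebrafish lateral
line; innate immune cells congregate at the damaged neuromasts within tens
of minutes. With neuromasts labelled green (e.g. *cldnB::GFP*) and
leukocytes red (e.g. *lysC::DsRED2*), inflammation can be scored per larva
either by counting red cells in a band around the horizontal myoseptum
(manual style) or, at scale, by measuring red fluorescence inside
automatically detected neuromast regions (automated style). This package
implements the automated pipeline end to end, the manual-analogue count
mode, and a synthetic image generator that makes every stage testable with
exact ground truth.

## Synthetic scene model

A larva is reduced to the features the pipeline consumes:

* **Body**: a band of half-height `body_half_height` (60 px at full frame)
  around a myoseptum axis running across the frame. Bright-field renders
  the band dark (600) on a light background (1000). Well-mounted larvae
  (probability `lateral_orientation_prob`, default 0.75) are tilted
  uniformly within ±4°; unfavourably mounted larvae are tilted ±25–55° and
  foreshortened so the body stays in frame.
* **Neuromasts**: `n_neuromasts` (default 7, valid 5–9) centres regularly
  spaced on the axis (spacing ≥ 4 rosette radii), each rendered as a ring
  of 8 Gaussian cell-spots (σ = 3 px, peak 2000) at radius 8 px — a rosette
  whose dimmer centre motivates the hole-filling step in detection.
* **Leukocytes**: Gaussian spots (σ = 3 px, peak ~N(1500, 200²) clipped).
  Controls receive Poisson(`baseline_count`, default 10) cells in a
  ventral/posterior stripe 8–`body_half_height` px below the myoseptum,
  biased to the rear 60 % of the body. Treated larvae additionally receive
  Poisson(r) cells per neuromast, uniform in a disc of 2 rosette radii
  around each centre, with r = `rmax`·d/(d + `k50`) for dose d (defaults
  rmax = 8, k50 = 1, so the default copper-like dose 10 recruits ≈ 7.3
  cells per neuromast) or r = `recruit_mean` (default 8) when no dose is
  given. The baseline counts near neuromasts are free parameters of the
  generator, not measured values.
* **Optics**: slice k of an odd-length stack (default 9; minimum 5) is the
  ideal image blurred with σ = `psf_sigma` + |k − central| ·
  `defocus_sigma_per_slice` (defaults 1.0 and 0.6 px) plus additive
  Gaussian noise (`noise_sd`, default 30 on the 16-bit scale). The true
  focal plane is always the central slice and is recorded in metadata.

Randomness uses one seed per plate with per-(replicate, well) spawn keys,
so extending a layout never perturbs previously generated wells, and
identical (layout, parameters, seed) give byte-identical stacks.

What the generator does *not* emulate: pigment, autofluorescence streaks,
anterior lateral line and gill/nose infiltration, rosette disintegration
after damage, z-dependent object visibility, time-lapse dynamics, optical
vignetting. Passing tests therefore demonstrate that the pipeline's logic
and statistics are correct under a controlled image model — not that the
detector thresholds transfer unchanged to any particular microscope.

## Pipeline choices

* **Autofocus**: variance of the Laplacian per slice, argmax, ties broken
  toward the middle slice. On generated stacks the true plane is recovered
  in 100 % of 50 seeds for any defocus > 0 at noise ≤ the default
  (σ = 30); by σ ≈ 80 noise variance swamps the sharpness signal and the
  metric fails, so noisier acquisitions should use the plate-wide
  first-well policy with a clean reference well.
* **Extended-focus projection**: per-pixel maximum over min(5, Z)
  contiguous slices containing the central plane; at stack edges the
  window is clipped and re-centred so five real slices are always used.
  Max projection is the natural operator for sparse bright objects on dark
  background; a per-pixel best-focus variant is available
  (`operator="best-focus"`) for dense scenes. Both fluorescence channels
  are projected identically.
* **Orientation QC**: principal axis of the largest dark bright-field
  component, pass if |tilt| ≤ 15°. The gate cleanly separates the
  generator's two mounting modes, with one caveat: a steeply tilted body
  that is strongly foreshortened and frame-clipped can occasionally read
  below 15°, so the measured pass rate (~80 %) slightly exceeds the 75 %
  mounting rate. The gate runs before detection; failed larvae are counted
  but never scored.
* **Neuromast detection**: median background subtraction → Gaussian
  smoothing (σ = 2) → Otsu threshold → hole filling → connected
  components → area gate [100, 4000] px² → circularity gate
  4πA/P² ≥ 0.4 → intensity-weighted centroid → square of side 48 px
  (≈ 3 rosette diameters) clipped to the frame. Squares overlapping by
  more than half the smaller square merge at the score-weighted centroid.
  All thresholds are package defaults tuned on the generator and exposed
  in `DetectionParams`; none is a measured property of the original
  screening software, whose analysis area was established empirically and
  never published.
* **Intensity score**: "relative" red intensity is defined as the square's
  mean minus the larva's own background (median of red pixels outside all
  squares), floored at 0 — the zero point is unstained tissue and the
  score is invariant to camera offset. Whether the original software
  background-corrected is unknown; this definition is declared rather than
  inherited.
* **Count mode**: DoG filter (σ 2/6), peaks ≥ 150 above background with
  ≥ 3 px separation, centre-of-mass refinement. Cells closer than the
  resolution limit merge into one detection, so dense recruited clusters
  are undercounted — the count remains monotone in dose, and the per-dose
  means of the two modes rank identically (Spearman ≥ 0.9 in the test
  suite). The band is 5 cell diameters (at 10 px per cell diameter) on
  each side of the estimated body axis, boundary inclusive, spanning the
  axis segment; counting is single-sided by construction in a 2D
  projection.
* **Statistics**: Welch's unpaired two-sided t-test (scipy's
  implementation behind the package surface, checked against the textbook
  closed form in the tests), mean ± SEM, minimum analyzable larvae 30
  (intensity) / 15 (count), star mapping with boundary P-values resolved
  toward the weaker claim (P = 0.05 → ns). No multiple-testing correction
  by default; Bonferroni is available behind a flag. Two identical
  constant groups are reported as t = 0, P = 1.

## Problem sizes used in validation

All desk-scale validation uses a reduced 220×360 px field of view with
5-slice stacks and full-scale objects (`small_scene()`), which preserves
per-neuromast statistics at a fraction of the rendering cost of the
1024×1300×9 default frame. The test suite checks detection fidelity on
50 + 50 seeded larvae, null calibration on 10,000 vectorised Welch
replicates, and screen sensitivity by drawing 200 subsamples of n = 30 per
group from pools of 120 pipeline-scored larvae per arm (control,
recruitment 8, recruitment 8×0.3) — with the assay's effect sizes the
subsampled power estimate is saturated and insensitive to the pool size.
The acceptance script simulates 100 independent triplicates of a 24-larva
condition (7,200 larvae through the full pipeline) and 500 larvae through
the orientation gate.

## Known limitations

* Detector defaults are calibrated to the generator's rendering scale; a
  real acquisition needs `DetectionParams`/`SpotParams` re-tuned on a few
  annotated wells.
* Count mode undercounts dense clusters (spot merging); intensity mode is
  the recommended readout under heavy recruitment.
* Orientation QC assumes the body silhouette is the largest dark object in
  bright-field; debris larger than the larva would defeat it.
* The dose–response form is a minimal saturating model; the generator
  makes no claim about real copper pharmacodynamics.
* One larva per well is assumed throughout; multi-larva wells are out of
  scope.
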