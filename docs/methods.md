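# Methods

This note documents the measurement model, the synthetic data it is
validated on, the parameters that matter, and the numerical choices —
in enough detail to reproduce or re-derive any behaviour of the
package.

## Measurement model

**Pulse thermography (PT).**  A flash pulse (order 10 ms, heating the
shell by well under 1 °C) is followed by an infrared recording of the
cooling surface at `frame_rate_hz` (default 100 Hz).  All processing
uses *relative* brightness only: emissivity is stored as 1.0 and never
used radiometrically, and every threshold in the pipeline is defined
relative to the image or row being processed, so the method is
invariant to detector gain and offset.  The single raw PT frame used
for egg segmentation is taken `delay_ms` = 600 ms after the flash,
where egg/background contrast is high but reflections have decayed.

**Pulse-phase thermography (PPT).**  For each pixel the cooling
transient over the window `[flash_frame_index + post_flash_skip, T)` is
transformed with the DFT (negative-exponent convention; no apodization,
matching a plain DFT of the transient), and the phase at bin k (default
k = 1) in degrees forms the phase image.  k = 1, the fundamental over
the cooling window, is the lowest available frequency and therefore the
deepest-probing thermal wave — the conventional choice for pulse
excitation; it is exposed as a parameter because nothing in the method
depends on it structurally.  `post_flash_skip` defaults to 1 frame to
drop the saturated flash frame.  Phases at bins whose magnitude is
below 1e−12 of that bin's image maximum are returned as NaN
("undefined") instead of numerical noise; a constant signal therefore
has an undefined phase everywhere except DC.

**Hybrid sizing (front view).**  Raw and phase images have
complementary sharpness (shell crisp in raw, chamber crisp in phase),
so the algorithm segments the egg in the raw frame (Otsu → largest
connected component → fill holes), segments the chamber inside the egg
in the phase image, then crops the phase image to the egg's bounding
rectangle with background forced to 0 and the within-egg minimum mapped
to 0 (the *hybrid image*).  On `n_rows` = 9 rows evenly spaced over the
central 80% of the chamber's row extent, the brightness profile is
smoothed with a cubic smoothing spline and the perimeter points P1
(left of the chamber-center column) and P2 (right) are located where
the profile crosses w_th = b_max/3 — one third of the row's maximum
smoothed brightness.  The threshold is a heuristic *fraction*, which is
what makes it transferable across eggs and acquisition settings.  A
direct least-squares conic fit constrained to an ellipse (minimum five
points; rotation fitted, not constrained) yields semi-axes a ≤ b in
pixels, converted with the calibration scale to a, b in mm,
A_b = πab in mm², and the single-view volume proxy A_b^{3/2} in mm³.

**Lateral view.**  With the egg's long axis horizontal and the dull
pole at the maximum-column side, the external profile of each row is
the last column inside the egg mask and the internal profile is the
last upward w_th crossing before it (the same one-third rule as the
front view — the natural analogue, since no separate rule is defined
for this profile; it is configurable).  The analysis is restricted to
the dull-pole region: rows whose external column is within
`dull_pole_band` = 10% of the egg length of the global maximum.  The
chamber height c is the mean external−internal gap over those rows.
If more than half of the region rows have a gap below 1 px (or no
internal crossing), the chamber is declared invisible
(`lateral_invisible`) and c is null — the real-data failure mode where
the cap is too thin or irregular to resolve.

**Quality flags.**  Two documented error modes are flagged, never
dropped: `near_perimeter` when the chamber approaches the egg boundary
closer than `d_min` = 3 px (the brightness transition degrades there),
and `holes` when filling the chamber mask grows its area by more than
`hole_frac` = 2% (internal cavities from shell defects).  `fit_failed`
marks any pipeline failure; flagged-failed rows are excluded from all
aging statistics and surface as N/A entries.

**Grading.**  `extra_fresh` iff c ≤ 4 mm and age ≤ 9 days;
otherwise `marketable` iff c ≤ 6 mm (both boundaries inclusive, "must
not exceed"); otherwise `not_marketable`.

**Calibration.**  Slot centers of the 10 mm-pitch, 4 mm-diameter
circular-slot grid are detected by Otsu binarization (slot polarity =
minority class), connected components, and intensity-weighted centroids
over a 2-px-dilated support (the dilation captures the feathered slot
edge; without it, centroids of slots at non-integer positions are
biased by up to ~0.06 px).  Grid axes come from nearest-neighbor
directions folded modulo 90° — a regular grid is an isotropic point
cloud, so PCA axes are degenerate and unusable.  The scale is
pitch_mm / (mean adjacent center distance), adjacency meaning pairs
within 25% of the median nearest-neighbor distance (grid axes only, no
diagonals).  Distortion is a single first-order radial model
r → r(1 + k₁r²) about the image center, estimated (optionally) by
minimizing the residual of the undistorted centers to a best-fit affine
grid; the default pipeline is scale-only (k₁ = 0), adequate for a long
lens at short working distance.

**Aging statistics.**  Standard deviations use the n−1 sample
estimator throughout (the "68% coverage" summary).  Repeatability =
per-egg-day mean, sd and sd as % of mean over ≥ 2 valid repeats.
Category summaries average a, b, c, A_b across the eggs of a size band
(M 53–63 g, L 63–73 g, XL > 73 g) per day, with ±1 sd bands; normalized
series divide by the first test day's value.  Weight loss is grams
relative to each egg's first test day (percent mode available).
Regressions are ordinary least squares on a polynomial basis — order 2
for normalized area vs weight loss, order 1 for normalized volume —
with R² = 1 − SS_res/SS_tot (undefined and flagged when y has zero
variance).

## Synthetic data

The generator produces thermogram sequences with exact ground truth;
it emulates the *contrast structure* the algorithm consumes, not the
underlying heat-diffusion physics.  After the flash frame, pixel
brightness is

    ambient + egg·A·e^(−t/τ_egg) + chamber·ΔA·e^(−t/τ_air)
            + Σ reflections·e^(−t/τ_refl) + N(0, σ)

with per-pixel area-coverage (3×3 supersampled) egg and chamber masks.
Defaults, chosen once as the study conditions:

| parameter | default | anchor |
|---|---|---|
| scale | 0.25 mm/px | 640-px-class MWIR camera framing one egg |
| flash amplitude A | 100 DL | stands in for the < 1 °C overheating |
| chamber amplitude ΔA | 100 DL | air heats more and cools faster than the interior |
| τ_egg | 0.7 s | post-flash surface response decays fast (t^(−1/2)-like); a sub-second constant also gives every pixel realistic fundamental-bin power |
| τ_air | 0.12 s | low thermal inertia of the air cap |
| noise σ | 2 DL = 2% of A | NETD ≈ 20 mK vs < 1 °C contrast |
| reflections | τ = 10 ms, 0.5–1 mm radius | the flash's own duration; bright in early raw frames, strongly attenuated in phase |

The egg outline is an ellipse (front) or two half-ellipses sharing the
vertical axis (lateral, blunter dull pole at max column); the lateral
chamber is the cap between the outline and the same outline with its
dull-pole semi-axis shrunk by c.  Aging cohorts follow a linear
weight-loss law (category-dependent rate) and a quadratic
normalized-area-vs-weight-loss law with negative curvature — near-linear
early growth that flattens late — plus configurable measurement noise;
with all noise terms at zero the emitted records satisfy the law
exactly, which the regression tests exploit.

What the generator does **not** emulate — and what passing tests
therefore do not show about real eggs: lateral heat diffusion and
optical blur (edges here are one pixel wide; real transitions are
wider, and the one-third rule's small outward bias grows with edge
width), shell texture and emissivity structure, non-elliptical chamber
shapes, egg-support geometry, and ambient drift beyond a constant.
Recovery accuracy on phantoms (median area error ≲ 3% at 1% noise) is
an upper bound on, not an estimate of, real-data accuracy.

## Numerical choices

* **Profile smoothing.**  The spline is a *linear* penalized cubic
  smoother (`make_smoothing_spline`), so symmetric profiles stay
  symmetric to machine precision; FITPACK-style knot-placement splines
  break that symmetry at the 0.1-px level.  The penalty λ is chosen by
  bisection so the residual RMS matches a robust noise estimate from
  second differences (1.4826·MAD/√6 — first differences confound slope
  with noise on smooth profiles).  On noise-free profiles this
  degenerates to near-interpolation.
* **Threshold crossing.**  The crossing *bracket* is detected on the
  smoothed profile (robustness to noise dips), but the sub-pixel
  *position* interpolates the raw samples of that bracket when they
  bracket w_th, falling back to the smoothed samples otherwise.  A
  global smoother necessarily widens the one-pixel chamber edge, and
  interpolating the widened edge at the one-third level biases the
  boundary outward by ~0.2 px per side (measured on phantoms); the raw
  samples retain the sharp edge.  An irreducible bias of ~1/6 px per
  side remains, intrinsic to thresholding a sharp edge at 1/3 instead
  of 1/2 of its height.
* **Tie-breaks.**  "Last pixel below w_th" uses strict `<`; P1 scans
  from column 0 up to the chamber-center column, P2 from the center to
  the row end.  A side with no crossing is omitted (logged), and the
  fit proceeds if ≥ 5 points remain.
* **Chamber segmentation without contrast.**  With Otsu thresholding, a
  split whose between-class variance fraction is below 0.75 is treated
  as "no chamber" (an Otsu split of pure Gaussian noise explains ~0.64
  of the variance; a real chamber > 0.9).  This returns an empty mask —
  flagged downstream — rather than hallucinating a chamber from noise.
  A fixed numeric threshold bypasses the check.
* **Degenerate inputs.**  Uniform frames, < 2-frame windows, NaN
  pixels, < 5 boundary points, collinear points, coincident grid
  centers and empty bounding boxes all raise typed errors; inside the
  batch pipeline every per-item error is converted to a `fit_failed`
  flag so one egg never aborts a batch.
* **Determinism.**  All generators are pure functions of (parameters,
  seed); pipeline outputs carry the resolved configuration in a
  provenance header and are byte-identical across re-runs.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data at the native phantom resolution (~200×200 px frames, 64-frame
sequences): 45 rendered acquisitions for the repeatability experiment,
20 phantoms for the recovery experiment, a 5×5 grid for calibration,
and 30 rendered acquisitions for the batch-pipeline test.  These sizes
were chosen as the smallest that exercise every code path at realistic
geometry; the statistics they produce are stable across seeds.

## Known limitations

* The volume proxy A_b^{3/2} is a monotone surrogate, not a calibrated
  volume; no 3-D reconstruction is attempted.
* The lateral height c inherits the dull-pole-band average, which
  slightly underestimates a spherical-cap height (the gap shrinks away
  from the pole); at the default 10% band the effect is a few percent.
* Distortion handling is first-order radial only; strong wide-angle
  optics would need a fuller camera model.
* Real acquisition hardware (flash synchronization, radiometric
  conversion, vendor formats) is out of scope; inputs are plain TIFF/
  PNG stacks with JSON sidecars.
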