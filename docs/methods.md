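# Methods

## The bias model

A line-scan sweeps the focal spot along a vessel segment at speed `V_scan`
(mm/s) and repeats every `T_line` (ms). Because pixels within a line are
acquired sequentially, two successive pixels are separated in time by
`T_pixel = X_pixel / V_scan`, and the time for a cell to move by `ΔX` from
one line to the next is really `T_line + ΔX / V_scan`, not `T_line`. All of
`kymoflow.correction` follows from this observation:

* transit time of the spot over a cell of extent `D` moving at `V`:
  `T_RBC = D / (V_scan ∓ V)` (− anterograde, + retrograde);
* apparent (shadow) size `D_app = V_scan · T_RBC`;
* apparent velocity `V_app = ΔX_mov / T_line = cot(α)` on axis-scaled
  image coordinates, related to the true velocity by
  `V_AA = V_scan·V/(V_scan − V)` and `V_AR = V_scan·V/(V_scan + V)`;
* the reciprocal identity `1/V_AR − 1/V_AA = 2/V_scan` coupling the two
  apparent speeds of the same cell.

Assumptions: constant scan speed over the analysed segment (acceleration
and deceleration at the segment ends are excluded from analysis, not
modelled), rigid 1-D cell extent along the vessel axis during one transit,
and a shadow width unaffected by the point-spread function. The model is
purely kinematic; it holds for any image-analysis method used to measure
the stripe slope.

Sign conventions: all speeds are magnitudes; the flow direction defines the
positive axis and the scan direction is an explicit enum. The anterograde
forward model has a pole at `V = V_scan` (the spot cannot overtake the
cell); inputs within 1e−6 relative distance of a pole raise an explicit
`SingularityError` rather than returning infinities that would silently
poison a pipeline. A retrograde apparent speed at or above `V_scan` cannot
arise under the model and raises `InconsistentObservationError`.

Units are fixed project-wide — µm, mm/s, ms — so 1 mm/s = 1 µm/ms and no
conversion constants appear in any formula.

## The simulator (and what it does and does not emulate)

`kymoflow.simulate` renders the acquisition from first principles: pixel
`(i, j)` samples the vessel at its own acquisition time
`t = i·T_line + j·T_pixel` (per sweep; a bidirectional line is a forward
sweep immediately followed by a mirrored backward sweep, with an optional
turnaround dead time, default 0). RBCs are top-hat occupancy intervals of
length `D` moving at constant `V`; pixel intensity is
`background · (1 − contrast · occupancy)` with fractional pixel coverage,
optional Gaussian PSF blur along the spatial axis, and Poisson or additive
Gaussian noise applied last. `T_line` includes a configurable fly-back
overhead (the hardware's fly-back duration is system-specific, so it is a
free parameter; the canonical recording uses 5%).

None of the closed-form bias equations enter the renderer — shadow widths
and stripe slopes *emerge* from the per-pixel timing. That makes the
simulator an independent oracle: the test suite verifies that measured
shadow widths match the size model within one pixel and stripe
displacements match the velocity model within 2% across a grid of speeds
and both directions.

`rbc_train` places cells at fixed spacing (linear density), optionally with
uniform spacing jitter. Strictly periodic trains produce Moiré-type
orientation aliases that real kymographs, with their irregular RBC
arrivals, do not have; extraction tests therefore use jittered trains
(jitter 0.4) as the realistic condition. The default jitter remains 0 so
that the geometry of a configuration is fully explicit.

What the simulator deliberately does not model: 3-D vessel geometry, RBC
deformation and tumbling, hematocrit-dependent cell interactions,
photobleaching, and scanner acceleration kinetics (an acceleration phase
can instead be excluded via the split `discard_fraction`, mirroring
practice). Passing tests therefore demonstrate correctness of the
*kinematic* analysis chain, not robustness to those biological and
instrumental effects.

The canonical synthetic recording (`standard_recording`) uses a 96 µm
segment at 0.4 µm pixels, 250 lines, 6 µm cells, a 0.6 µm PSF and a train
spacing of `max(12 µm, 1.2 × apparent displacement per line)` — sizes
chosen so stripes of any measurable speed remain resolvable while a full
extraction runs in well under a second.

## Stripe-speed estimation

For each analysis window (default 1 s of lines; incomplete trailing
windows are dropped, and a recording shorter than one window is analysed
whole) the stripe slope `s` (columns per row) is estimated in two stages:

1. **Global localization by consecutive-row correlation.** The summed
   FFT cross-correlation between each row and the next peaks at the
   per-line displacement in pixels. The acyclic correlation is normalized
   by the overlap length (the raw version biases wide shadows toward
   smaller lags), the first sufficiently strong local maximum is taken
   (alias peaks from near-periodic trains always sit at *larger* lags than
   the physical displacement), and the peak is refined to subpixel by
   parabolic interpolation. This estimator stays sharp at any steepness:
   its peak width in slope units is roughly the shadow width divided by the
   window height, independent of `s`.

2. **Local refinement by the chosen criterion.** Within ±1.5 of the
   correlation estimate, a 41-point slope grid is scored by either SVD
   separability (energy fraction of the first singular value of the window
   rotated so stripes become vertical) or Radon projection variance, and
   the best interior point is polished by bounded scalar minimization to an
   angle tolerance of 1e−4 rad (mapped to the local slope scale). The
   criteria carry orientation information only for shallow stripes; beyond
   ~8 columns/row their rotation-resampling bias exceeds the correlation
   estimator's error, so the refinement is applied only below that slope
   and the correlation estimate is used directly above it. An exhaustive
   angle-grid search is *not* used: for steep stripes the alignment peak is
   orders of magnitude narrower in angle than any practical grid step.

The speed follows from the axis scaling, `v_app = (X_pixel/T_line)·s`.

**Flow detection.** A window is flagged (and excluded from the recording
mean) only if three complementary detectors all fail: the criterion score
exceeds a row-shuffled surrogate's score by less than 0.1 (informative for
shallow stripes), the correlation-peak prominence — measured on a
variance-stabilized curve, excluding the peak's own flanks — is below 5
(informative for steep stripes), and the absolute separability is below 0.5
(informative for stationary patterns, for which row shuffling is an
invariance). Pure-noise windows score well below all three thresholds
(prominence ≤ ~4 by extreme-value statistics of ~200 lags); a smooth but
static background can legitimately pass as "zero flow". If every window is
flagged the extraction raises rather than returning a meaningless mean.

**Physical limits.** A stripe is only measurable while a shadow appears on
two successive lines, which requires an apparent displacement per line
below the segment length. Since that displacement is at least
`(V_app/V_scan) ×` segment length, anterograde measurements are impossible
for `V ≳ V_scan/2` on *any* geometry — the quantitative form of the
practical advice that fast flows should be scanned retrograde, where no
such ceiling exists.

## Size and diameter measurements

Apparent shadow size: rows are binarized at the midpoint between the
background and shadow intensity modes (Otsu split, then class means); dark
runs touching the image border are discarded, and the median run length
across rows is converted to µm. Accurate to one pixel on clean images.

Vessel diameter: after a 3×3 median filter, the intensity profile
perpendicular to the vessel axis (chosen as the marginal-mean profile with
the larger variance, or fixed by the caller) is reduced to its full width
at half maximum with subpixel linear interpolation of the crossings. FWHM
was chosen because "width of the fluorescent plasma" is not otherwise
operationalized; for a dye-filled lumen with a flat-topped profile, FWHM
equals the lumen width to within a pixel. A 1-pixel-wide band cannot
survive the 3×3 median filter, so the narrowest measurable vessel is two
pixels; flat images raise a no-plateau error.

## Scan-speed recovery fit

`fit_vscan` fits `V_AA = V_scan·V_AR/(V_scan − 2·V_AR)` to paired apparent
speeds by minimizing the unweighted chi-square with Levenberg–Marquardt
(no per-point measurement variances are assumed), initialized from the
closed-form reciprocal identity `V_scan⁰ = 2/median(1/V_AR − 1/V_AA)`,
which places the start on the correct side of the model pole
(`V_AR = V_scan/2`). Pairs with `V_AR ≥ V_AA` are inconsistent with the
model, reported, and excluded. The test suite cross-checks the minimizer
against an exhaustive 10⁵-point grid search of the chi-square.

The p < 0.05 confidence interval uses a heteroscedasticity-consistent
(sandwich) variance rather than the plain least-squares covariance: the
measurement scatter is multiplicative and enters through the *predictor*
`V_AR` as well as the response, and the model's sensitivity to `V_AR`
grows sharply toward the pole, so the naive covariance understates the
uncertainty several-fold (simulated coverage ~45% instead of 95%). The
sandwich form — common relative-noise level estimated from standardized
residuals, propagated through both observables, t-quantile on n−1 degrees
of freedom — achieves 99–100% coverage in the regimes the validation
experiment uses.

## The synthetic validation experiment

`run_validation_experiment` emulates the bidirectional in-vivo protocol
with known ground truth: 38 vessels assigned round-robin to scan speeds
{5, 10, 15, 20, 40} mm/s, true velocities uniform on 0.5–15 mm/s capped at
0.8·V_scan (avoiding the anterograde pole), and each apparent speed
perturbed by independent multiplicative Gaussian noise with cv 0.02 — the
scatter scale of windowed stripe-slope estimates. Two checks follow:

1. per scan speed, the consistency-model fit recovers `V_scan`; recovered
   vs true scan speeds are regressed (slope 1 under the model);
2. each pair's two apparent speeds are corrected independently and the two
   corrected sets regressed against each other (slope 1 under the model).

Both regressions use a free intercept and report slope ± standard error.
The corrected-velocity slope is tight (±0.01 typically); the scan-speed
recovery slope scatters more (roughly ±0.04 across seeds) because only ~8
pairs inform each of five fitted points. Per-pair, the two corrected
velocities agree to within the propagated noise
`3·cv·(s_A + s_R)`, where `s_A = 1/(1 + V_AA/V_scan) ≤ 1` damps the
anterograde noise and `s_R = 1/(1 − V_AR/V_scan)` amplifies the retrograde
noise toward the pole — a flat `3·cv` bound holds only in the slow-flow
limit.

## Numerical choices and degenerate inputs

* Pole guard band: 1e−6 relative; closer inputs raise the pole error.
* Angle refinement tolerance: 1e−4 rad, mapped to slope units locally.
* Shadow threshold: Otsu split then two-class-mean midpoint (no explicit
  binarization recipe is standard; this is mode-midpoint thresholding).
* Zero-velocity cells give exactly vertical bands and `v_app = 0`; empty
  or constant images raise explicit no-shadow / no-plateau errors.
* Bidirectional splitting discards a configurable fraction (default 5% in
  the CLI) of each sweep's ends, the standard guard against scanner
  acceleration; the backward half is mirrored so position always increases
  left-to-right downstream.
* All stochastic components (noise, jitter, surrogate shuffles, the
  validation experiment) derive from explicit integer seeds; identical
  seeds give bit-identical images and tables.

## Known limitations

* The extraction assumes a single dominant flow direction per window and
  non-negative displacement (flow defines the axis); reversing flows would
  need a signed search range.
* Correlation-based localization assumes consecutive lines see the same
  cells; at apparent displacements near the segment length (the anterograde
  ceiling) sightings become rare and windows are conservatively flagged.
* The quality gate can accept a static structured background as zero flow;
  it cannot distinguish "no cells" from "cells not moving".
* Measured diameters and sizes are intensity-threshold quantities; they
  inherit any PSF broadening of the real optics, which the model
  deliberately neglects.
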