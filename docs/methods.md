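# Methods note

This note records the quantitative model implemented by `leadassay`, the
parameter choices with their rationale, what the synthetic data generator
does and does not emulate, and the numerical decisions that affect results.

## Measurement principle

A whole-cell bacterial biosensor responds to dissolved lead by expressing a
reporter enzyme that cleaves a chromogenic substrate, turning the well blue.
A single-board camera photographs a 16-well sample holder under sequential
red, green and blue LED illumination on a fixed cadence (every 40 minutes
over 17 hours by default). The analysis converts each well's colour to HSV
and uses the **saturation** component (0–100 scale) as the observable: it
tracks colour purity and is far less sensitive than raw RGB to the absolute
light level.

Each assay carries its own calibration wells at known lead concentrations
(nominally 0, 10, 20, 50 and 100 ppb). Quantification is always relative to
these co-measured wells, which absorbs batch-to-batch and temperature
variability in bacterial growth.

## Imaging chain

1. **LED exposure calibration.** For each channel the exposure setting is
   scaled by `C = AEC · target/white_mean` with reference exposure
   `AEC = 100` and target mean `200` (native 8-bit counts), computed from
   the central region of a white-reference frame per LED. This white
   balance removes per-LED brightness imbalance.
2. **Flat fielding.** Each calibrated sample frame is divided by the
   calibrated white frame and rescaled to the target level,
   `I = I_raw · 200 / I_flat`, clipped to [0, 255]. Zero-valued flat pixels
   are substituted with the target level and a warning is raised; clipping
   also warns. Flat fielding removes spatially heterogeneous illumination,
   which otherwise biases per-well saturation (the three LEDs illuminate
   the holder from different positions, so the gradients differ per
   channel and do not cancel in the saturation ratio).
3. **ROI placement.** A printed square fiducial marker anchors the well
   ROIs: each well's box is stored as offsets and sizes in units of the
   marker edge length, so one layout works at any camera distance. The
   marker also carries a short metadata payload (assay id, device id).
   Wells may carry absolute pixel coordinates as a fallback for frames in
   which the marker cannot be decoded.
4. **ROI statistics.** Per channel, the ROI mean and the standard error of
   the mean `sigma = sd / sqrt(n_pixels)` (sample sd, ddof = 1).
5. **HSV decomposition.** Standard hexcone conversion with hue in degrees,
   saturation and value in percent. Uncertainties on H, S, V come from
   first-order (delta-method) propagation of the per-channel standard
   errors through a central-difference numerical Jacobian (step
   `1e-5 · 255`), treating the channels as independent. At zero chroma the
   hue is undefined and its uncertainty is reported as NaN with a warning.

## Device saturation calibration (optional)

Measured saturation depends on the unit's optics and illumination. A
printed wheel of digitally defined colours calibrates each device:
measured saturation `y` versus digital saturation `x` is fitted with

    y = a · exp(−b·x) + c

and inverted, `x = −ln((y − c)/a)/b`, to map measured saturations onto the
digital scale. Both orientations are supported (`a < 0` gives the usual
rising, plateauing response; `a > 0` a falling one); the fit requires
`b > 0` and a monotone curve. `sigma_x` combines the measurement error and
the full 3×3 parameter covariance to first order.

## Kinetics

Every well's baseline-subtracted saturation series is fitted with a
double sigmoid,

    y(t) = a / (1 + exp((b − t) · c / (1 + exp(−t/τ))))

* `a` — amplitude (max saturation, percent),
* `b` — half-rise time in minutes (`y(b) = a/2` exactly),
* `c` — slope (per minute),
* `τ` — inner growth-gate time scale, default 1 minute. With `t` in
  minutes the inner sigmoid saturates within minutes, so by default the
  gate is effectively constant; `τ` is exposed for slower gating but its
  physical identification is an open question and it is not fitted.

**Baseline subtraction.** The first frame is subtracted from every frame of
the same well (`sigma_sub = sqrt(sigma_1² + sigma_i²)`), so every assay
starts at zero saturation regardless of initial tint.

**Fitting.** Weighted (1/σ²) bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobian), bounds
`a ∈ [0, 120]`, `b ∈ [0, 10·t_end]`, `c ∈ [0, 1]`. Initialisation:
`a₀ = max(series)`, `b₀ =` first time at half max, `c₀ = 4/t_range`, with
a deterministic multi-start over `b₀ ∈ {default, t_end, 2·t_end}` because
no-growth wells have their half-rise beyond the observation window where a
single in-window start can strand the optimiser. Covariance is
`(JᵀWJ)⁻¹`; reduced chi-square uses `n − 3` degrees of freedom; an
unweighted fit (all sigmas zero) scales the covariance by the residual
variance.

**Final saturation.** The well's result is `y(t_end)` with variance
`gᵀ C g + sigma_baseline²`, where `g` is the analytic parameter gradient,
`C` the fitted covariance and `sigma_baseline` the measurement sigma of the
first (subtracted) frame. The second term is a deliberate extension: the
first frame's error offsets the whole subtracted series coherently, so the
fit cannot average it away; omitting it under-reports the final-saturation
sigma by roughly a factor of two in simulation (reported 0.21 vs realised
scatter 0.44 at series noise 0.4).

## Data-quality cuts

1. `b > 1000` min → the well failed to grow (`failed_growth`).
2. Final development below 2.0 saturation points → `failed_growth`. This
   floor is a robustness extension: a flat no-growth series has two
   equal-cost fit explanations — a huge half-rise time (caught by rule 1)
   or a degenerate tiny amplitude already risen (`b ≈ 0`, missed by
   rule 1). Growing wells develop ≥ ~6 points; no-growth wells < 0.1.
3. If the 100 ppb calibration well ends below the 50 ppb well (growth
   inhibition at high lead), the 100 ppb point is dropped from the lead
   curve only (`dropped_top_point`); the well itself is not failed.
4. More than one `failed_growth` calibration well disqualifies the assay:
   no concentrations are reported.

## Quantification

The passing calibration wells' final saturations versus nominal ppb are
fitted with a weighted first-order polynomial `y = a·x + b` (closed-form
normal equations). Each passing unknown well is inverted,
`x = (y − b)/a`, with variance from the measurement sigma plus the full
2×2 curve covariance (slope–intercept cross term included). Guards:

* `|slope| ≤ 0.01` %/ppb → the assay response is flat (the full 0–100 ppb
  span changes saturation by under one point, below the noise floor) and
  quantification refuses rather than divides by ~0;
* negative concentrations clamp to 0 ppb; the raw value is retained and
  the sigma is never altered by clamping;
* results above 100 ppb are flagged `above_validated_range` (the method is
  validated below 100 ppb; users should dilute 1:10 for suspected
  100–1000 ppb samples). Dilution bookkeeping multiplies the value and
  sigma by the dilution factor.

**Water matrix.** Lead curves are prepared in de-ionised water; tap water
slightly impedes growth. A fixed ratio (default 1.08) divides de-ionised
saturations, preserving the relative error:
`S_tap = S/1.08`, `sigma_tap = S_tap · sigma/S`. `estimate_matrix_ratio`
recomputes the ratio for a different water as the grid-mean pointwise
ratio of two fitted response curves. The 1.08 default is an empirical
constant of the original de-ionised/tap comparison and is not derivable
from data in this repository.

## Accuracy statistics

Repeated measurements at a known concentration are summarised by the mean
with a two-tailed Student-t confidence interval,
`CI = mean ± t(conf, n−1) · sd/sqrt(n)`; sample sizes here are far below
the n ≈ 30 where a z interval would be defensible. With only two repeats
the interval (and p-value) is declined as not meaningful — the mean and
raw values are still reported. The p-value is a two-tailed one-sample
t-test of the mean against the nominal value and is flagged provisional:
it is one defensible recipe, not a uniquely determined one. Agreement with
a reference method across samples is quantified with the Pearson
correlation coefficient.

## Synthetic data generator

Everything the hardware produces is emulated with known ground truth, so
the full pipeline is testable without a device or wet lab.

Emulated:

* frame triplets (one per LED) plus white-reference frames, 8-bit
  quantised, on the acquisition cadence;
* per-well double-sigmoid saturation trajectories (half-rise ~480 ± 20 min,
  slope 0.012/min) with Gaussian measurement noise (sd 0.4 saturation
  points per timepoint at the ROI-mean level — per-pixel noise is scaled
  by sqrt(n_roi_pixels) so ROI averaging reproduces exactly that sd);
* a monotone saturating concentration→amplitude response
  `a(ppb) = 6 + 256·ppb/(1500 + ppb)`: ~22 points of final saturation at
  100 ppb, a basal ~6-point 0 ppb response, and only mild curvature over
  the validated 0–100 ppb range (consistent with the observed near-linear
  lead curves — the half-saturation constant sits far above the assay
  range). This mapping is a generator property only; the pipeline never
  sees it;
* per-channel linear illumination gradients with different orientations
  (the three LEDs sit at different positions) plus a fixed per-LED
  exposure imbalance — this is what makes flat fielding consequential,
  since saturation is invariant to channel-uniform scaling;
* the fiducial marker with a metadata payload;
* failed-growth wells (half-rise pushed to 1400 min).

Not emulated: optical blur and chromatic aberration, camera noise models
(read/shot noise, hot pixels), condensation and meniscus effects, well
cross-talk, biological variability beyond the half-rise jitter, JPEG
artefacts (frames are written as lossless PNG), and any hue/value drift
during development (hue is fixed at 200°, value at 68%).

All randomness flows from the single spec seed through named child
streams (string keys hashed with CRC-32, which is stable across
processes); renders are byte-identical per seed.

## Numerical choices

* Exponent clamp ±350 in the growth model and its gradient: overflow-safe
  for `exp(z)²` in float64 while leaving the model unchanged to machine
  precision in the observable range.
* Matrix inversions use `inv` with a `pinv` fallback for singular normal
  matrices.
* Printed-table comparisons use round-half-away-from-zero at 1 decimal,
  matching the convention of the reference values.
* Derived RNG seeds are kept below 2³¹ everywhere.

## Limitations and open questions

* The inner-gate time scale `τ` is fixed, not fitted; its physical
  identification is unresolved.
* One reference-table hue (ROI 5) and one value digit (ROI 7) disagree
  with recomputation by one unit of the last printed digit; treated as
  printed-value precision, not conversion errors.
* The de-ionised→tap ratio (1.08) and the validated-range edge (100 ppb)
  are empirical constants taken as given.
* The p-value recipe in the accuracy summary is provisional (see above).
* The linear lead curve is an empirical approximation; it extrapolates
  poorly outside the calibrated 0–100 ppb span, hence the validated-range
  flag and the slope floor.
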