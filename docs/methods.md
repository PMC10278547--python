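# Methods

This note documents the models implemented in `hmdcal`, the choices made
where the design was genuinely open, and what the virtual display does and
does not emulate.

## Colorimetry

Conversions are the CIE 1931 standard forms: `xyY → XYZ` with
X = xY/y, Z = (1 − x − y)Y/y; `XYZ → xyY` by normalising against X + Y + Z;
L\*a\*b\* and L\*u\*v\* with the cube-root/linear branch at (6/29)³.
Luminance Y is carried in cd/m² everywhere; nothing rescales it implicitly.

A second conversion convention, `mode="strict_paper"`, reproduces a
published variant of the xyY→XYZ equations literally (Y divided by 100, no
/y on Z). It exists purely for auditability: the standard forms are the ones
whose round trip is the identity and which make the calibration
self-inverting, so they are the default and the only forms used internally.
The two agree on X for all inputs and differ by the factor 100 on Y and the
factor y on Z.

ΔE defaults to CIE76 (Euclidean distance in L\*a\*b\*) because the
perceptibility bands used for validation (< 1 imperceptible, 1–2 close
observation, 2–10 at a glance) are quoted against that scale; CIEDE2000 is
selectable and verified against the published Sharma et al. test pairs.
The reference white for L\*a\*b\* is the session's measured white point —
device output is being compared with device output, so a standard illuminant
would be the wrong anchor. D65 is the fallback when no session white exists
(the sRGB swatch encoder).

`XYZ_to_sRGB_display` exists only to render report swatches. It uses a
plain XYZ-ratio white adaptation, not a chromatic adaptation transform;
out-of-gamut values are clipped and flagged, never silently.

## Spectral analysis

The CIE 1931 2° color-matching functions are evaluated analytically with
the multi-lobe piecewise-Gaussian fit of Wyman, Sloan & Shirley (2013),
accurate to about 1% of peak. At the tolerances the spectral route is used
for (chromaticity within 0.005 of the locus for a monochromatic line,
within 0.01 for a narrow primary) this is ample, and it avoids shipping a
numeric table of uncertain provenance. `spd_to_XYZ` integrates by the
trapezoid rule and scales by Km = 683 lm/W, so Y is in cd/m² when the input
is absolute spectral radiance.

Channel constancy follows the peak-ratio definition: c_x is the ratio of
the shade's spectral peak to the 0.1-shade reference peak, and the error e
is the mean squared residual between c_x·φ_ref and φ_x. Two choices were
open:

* **Normalisation.** Published constancy errors are small dimensionless
  numbers, which implies some normalisation that is never stated. All
  spectra are divided by the reference peak before the MSE, making e
  dimensionless and comparable across devices. Because of this ambiguity,
  constancy is validated by property (e = 0 under exact scaling; equality
  with a brute-force summation oracle under distortion), not against any
  printed value.
* **Estimator.** The peak ratio is the stated definition and the default;
  a least-squares projection coefficient is exposed as
  `estimator="lstsq"` because the MSE is sensitive to this choice.

When grids differ, spectra are linearly resampled onto the coarser grid
restricted to the common support. Peak ties break toward the shorter
wavelength.

## Tonal-response fitting

The clipped-linear model L(x) = min(m·x, t) is fit by a deterministic
breakpoint grid search: for every split of the ramp into a linear prefix
and a saturated suffix, the slope has the closed form Σx·L/Σx² and the
threshold is the suffix mean; the best split by RSS is then polished with a
bounded least-squares solve. This is exactly checkable against a
brute-force oracle, unlike a generic nonlinear optimizer. Conventions for
the degenerate cases:

* No detectable clipping (the best breakpoint sits at or above the top
  level): t is reported as +∞, flagged unsaturated.
* Flat from the first level (the autoexposure signature): t is the mean
  luminance and m = t/x₁, the minimal slope consistent with saturation at
  the first level, flagged `exposure_saturated_`.

At 1% relative luminance noise the recovery accuracy is noise-limited by
the number of points on the linear branch: with only 2–4 linear points the
slope estimate's standard deviation is ≈ 0.7–1.3%, so a 3% bound holds
through the 99th percentile of random ramps but cannot hold for every
single trial. Tests and the acceptance script therefore bound the mean and
the 99th-percentile error (3% on m, 5% on t).

The power-law model L = k·x^γ is fit by ordinary least squares in log–log
space and is exact on noiseless power-law data.

Additivity ratios exclude levels where the white luminance is below
0.01 cd/m² (division blow-up on dark readings); excluded levels are listed
in the result, never dropped silently.

## Calibration and inversion

The primary matrix M minimises Σ‖XYZᵢ − M·RGBᵢ‖² over the measured
primaries (numpy lstsq; with exactly the three primaries it interpolates,
so M's columns are the primaries' XYZ). The forward model is
XYZ = M·ρ(drive) with ρ the per-channel tonal response normalised to
ρ(1) = 1: identity in default mode (naive matrix calibration — deliberately,
since demonstrating its failure under the default pipeline is part of the
protocol), the power-law fit when tonemapping is disabled, the
clipped-linear fit in selective mode.

The radial chromaticity correction
α̃(xy) = xy_w + (xy − xy_w)/(1 + B·|xy − xy_w|) pulls predictions inward
toward the measured white with strength B (default 0.01, exposed as a
parameter; refitting it per device is possible but not automated). It is a
strict radial contraction that preserves direction from the white point.
Design choices around it:

* **Inverse.** The radial map r ↦ r/(1 + B·r) inverts in closed form to
  r′ ↦ r′/(1 − B·r′), valid for every corrected point (their radius is
  below 1/B by construction). The closed form is used rather than a
  numerical bisection — it is exact, and the round trip is tested at 1e-12.
* **Anchor.** xy_w is the session's measured white (the display at full
  drive), not a standard illuminant: the correction describes device
  behavior relative to device output.
* **Where it applies.** Only in tonemap-disabled mode, where the
  gamma-uncorrected path produces the inward drift it models. Measured
  primaries are de-compressed (inverse α̃) before fitting M, so M estimates
  the underlying mixing matrix and predictions re-apply α̃; this makes
  calibration and correction mutually consistent and the closed loop exact
  on the simulator.

Inversion (`rgb_for_target` / `DisplayCalibrator.transform`) converts the
target to XYZ (from xyY directly, or from L\*a\*b\* under the session
white), applies the inverse correction where active, maps through M⁻¹, and
inverts the per-channel response (u^(1/γ), or u·t/m on the clipped-linear
branch with the smallest drive returned for saturated intensities).
Components outside [0, 1] are clipped **and flagged** — stimulus validity
is the whole point of the tool, so out-of-gamut targets are never clipped
silently. The scalar clipped-linear luminance map (for achromatic targets
driven through a single channel) binds to the same session's fitted
response, the W-channel fit for achromatic work.

Validation uses the 16 corners of the nested cubes [0.2, 0.8]³ and
[0.4, 0.6]³. Sixteen corners are emitted even though parts of the protocol
description speak of "eight" values: two cubes have 16 distinct corners,
and validation indices beyond 8 are meaningful (the all-high corners of the
two cubes are the white and gray points). Order is deterministic: within
each cube a Gray-code path from the all-low to the all-high corner
(adjacent corners differ on one axis), big cube first, so the achromatic
corner of each cube lands at indices 7 and 15.

## The virtual display

`DisplayModel` is a parametric stand-in for a headset plus engine pipeline:
three primaries (peak luminance plus a spectral basis of one or two
Gaussian lobes per primary — two lobes mimic dual-panel devices whose
primaries show multiple peaks), a native panel gamma, a tonemap, an
autoexposure stage, measurement noise (relative on luminance, absolute on
chromaticity, seeded), and a radial chromatic compression. When a primary's
(x, y) is not given explicitly it is derived by integrating the spectral
basis against the 2° observer, which keeps the spectral and colorimetric
routes exactly consistent.

Pipeline order per reading: autoexposure → tonemap → per-channel response →
mixing through the primary matrix → xyY (+ compression, + noise). The three
protocol configurations map onto it as:

| mode | autoexposure | tonemap | response | compression |
|---|---|---|---|---|
| default | saturating gain (10) | filmic | linear | off |
| tonemap_disabled | off | off | x^γ (native) | B = 0.01 |
| selective | off | countered (net identity) | clipped linear | off |

Choices worth recording:

* **Tonemap curve.** Engine tonemappers are proprietary; the simulator uses
  the fixed rational curve τ(v) = (1+c)v/(1+cv), c = 4 — monotone,
  τ(0) = 0, τ(1) = 1, concave and therefore subadditive. A rational
  ACES-style approximation was considered and rejected: its toe makes the
  curve superadditive at low levels, which would invert the additivity
  signature the simulator exists to reproduce. τ is applied as a
  luminance-ratio scale (all channels share the factor τ(Y_rel)/Y_rel), so
  chromaticity is preserved while the brighter combined-white stimulus is
  compressed harder than single channels — this is precisely what makes
  (L_R + L_G + L_B)/L_W exceed 1 with tonemapping on, and equal 1 exactly
  for any linear pipeline.
* **Autoexposure** is a memoryless gain-and-clip (gain 10 ⇒ every ramp
  level from x = 0.1 up saturates), not a temporal adaptation loop. It
  reproduces the default-mode artifacts: ramps flat from the first level,
  and every shade of a channel collapsing onto the same spectrum (scaling
  factors ≈ 1). It is deliberately crude; it models the signature, not the
  dynamics.
* **Chromatic compression** models the observed inward drift of measured
  chromaticities relative to matrix predictions on the gamma-uncorrected
  path. No mechanism for it is established, so the simulator implements it
  as exactly the α̃ form with the default strength 0.01 — which makes the
  α̃-corrected calibration the correct model for this display, by
  construction. The reported secondary luminance spike of some dual-panel
  devices in default mode has no stated mechanism either and is **not**
  modeled.
* **Presets.** Five fictional device files span the observed regimes
  (bright AMOLED, dim OLED, mid OLED with top-end clipping, broad-primary
  LCD, dual-panel bimodal). They are illustrative fixtures, not claims
  about real products.

What passing tests on the simulator do **not** show about real hardware:
panel non-uniformity, off-axis measurement error, temporal adaptation of
autoexposure, inter-eye differences, and any engine-exact tonemap shape.
The closed-loop ΔE ≈ 0 results are exactness checks of the math (the
simulator is model-matched by construction); the hardware-relevant claims
are the qualitative signatures (subadditivity direction, saturation
artifacts, constancy behavior) and the noise-robustness bounds.

## Problem sizes and determinism

All tests and the acceptance script run on the 10-level/4-channel/16-cube
protocol with spectra on a 380–780 nm, 4 nm grid; property checks use
100–10,000 random instances and the ramp-recovery study uses 500 ramps.
Every stochastic component draws from a seeded generator; with noise at 0
the simulate → characterize → calibrate → validate loop is bit-reproducible,
and with noise on it is bit-reproducible for a fixed seed.

## Known limitations

* Single-patch calibration only (one measurement spot, one eye); no
  spatially varying or per-eye model.
* The sRGB swatch path uses a ratio adaptation, not a CAT; swatches are
  illustrative.
* B is a fixed scalar; a per-device refit would need measured cube data
  and is left to the user.
* The CMF analytic fit is a ~1% approximation; work needing
  instrument-grade spectral integration should substitute a measured table
  via the `cmf` argument of `spd_to_XYZ`.
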