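# Methods

This note documents the models, numerical choices and limitations behind
`sampam`, in the spirit of a methods appendix: what is simulated, what is
measured, and what the synthetic results do and do not demonstrate.

## Phantom and acoustic forward model

The phantom is a stack of plane-parallel layers, by default
water (0.5 mm, 1500 m/s, Z = 1.48·10⁶ kg m⁻² s⁻¹),
1 % agarose (0.3 mm, 1520 m/s, 1.58·10⁶),
skin (1.4 mm, 1550 m/s, 1.65·10⁶),
polyamide film (124 µm, 2620 m/s, 3.1·10⁶) and
a polystyrene dish bottom (2350 m/s, 2.47·10⁶).
The water and agarose impedances and the skin sound speed and thickness
range (1.3–1.5 mm) are the sample's measured/literature values; the skin
impedance is a typical soft-tissue figure and the film/dish constants are
standard polymer values. Inside the skin sit two structure types:

* **Pigment cells** — absorbing disks, diameter uniform in 10–100 µm,
  placed uniformly at random within the skin (margin of one radius so each
  cell fits). Their absorption amplitude defaults to 1; the skin layer
  itself carries a background absorption of 1/14, so the default phantom
  reproduces the ≈14:1 absorber-to-background photoacoustic contrast of
  pigmented skin.
* **Scale inclusions** — thin stiff ellipsoids (default semi-axes
  250×180×12 µm, impedance 2.2·10⁶ > skin) in a shallow "shingle"
  sub-layer between 20 % and 50 % of the skin depth. The scale impedance
  is a free parameter: no quantitative scattering amplitude for scales is
  available, only that they reflect strongly.

**Forward model.** First-order ray acoustics: every impedance step and
scale top surface contributes one echo with amplitude
`R = (Z₂−Z₁)/(Z₂+Z₁)` at its round-trip travel time (SAM); every absorber
contributes one pulse of amplitude proportional to its absorption at its
one-way travel time (PAM). No multiple reflections, no refraction, no
frequency-dependent attenuation (a single exponential amplitude decay per
path length is available, default off). Events are deposited onto the time
grid with linear sub-sample splitting, blurred laterally by a Gaussian PSF
(FWHM = λ·f-number ≈ 75 µm for SAM; 10 µm for PAM, the system's optical
spot), and convolved with the transducer pulse. The lateral blur uses
nearest-edge boundary handling so a uniform layer stays uniform to the
image border (the sample extends beyond the scanned area). PAM can append
a weak dish-bottom echo replica of each source (extra path: down to the
film/dish interface and back, scaled by that interface's |R|), emulating
the weak second arrival seen behind the skin signal.

**Pulse and bandwidth.** The pulse is a Gaussian-modulated cosine at
40 MHz. Its fractional bandwidth is defined as the −6 dB (half-amplitude)
full width of the amplitude spectrum over the centre frequency; with
σ_t = 2.3548/(2π·b·f₀), the one-way envelope FWHM in depth is
2.3548²·v/(2π·b·f₀). The default b = 0.97 puts this at ≈34 µm in water,
the middle of the system's measured 33–35 µm axial resolution; this
calibration, not the nominal transducer datasheet, fixes the default.

**Noise.** Additive white Gaussian noise of std `noise_std/√repeats`
(default 0.05 and 32 repeats) models the digitizer's averaged
acquisitions directly rather than averaging 32 simulated realizations; the
√N reduction is therefore exact by construction and is verified at the
volume level. All randomness (placement, both modality noise streams)
derives from one seed via independent substreams, so identical
(config, seed) gives bit-identical volumes.

## Processing chain

* **Bias subtraction** uses the mean of the first 64 pre-trigger samples
  per A-line, not the whole-trace mean, so a genuine unipolar
  photoacoustic signal cannot bias the baseline.
* **Envelope detection** is the magnitude of the analytic signal
  (`scipy.signal.hilbert`). For pulses shorter than about one carrier
  cycle the analytic-signal envelope deviates from the true modulation in
  the far tails; tests therefore assert envelope accuracy on interior
  samples of sufficiently narrowband pulses.
* **Co-registration** maps absolute time (trigger delay included) to depth
  with `z = vt/2` (SAM) and `z = vt` (PAM) at a single sound speed
  (default 1500 m/s; 1550 m/s appropriate inside skin) — no per-layer ray
  tracing. Both envelopes are linearly resampled onto the overlap of their
  depth ranges at the finer native spacing (the SAM grid, v/2f_s). The
  `reference` switch relabels the common axis as depth, round-trip time or
  one-way time; the three are equivalent up to scaling, and depth is the
  default because it is the physically meaningful axis. Linear
  interpolation suffices because envelope data is smooth after detection.
* **Windowing** is explicit; an `auto` helper brackets the strongest
  envelope peak with configurable guard margins, standing in for the
  study's manual window choice.

## Statistics

C-scans are per-pixel maxima over a depth window; B-scans are exact
slices. Histograms rescale the volume to [0, 255] by its global maximum
(fixed-range mode available) and use 256 unit bins, making counts
invariant to global amplitude scaling. The occupancy threshold is not
recoverable from any published number, so the default is
mean + 3·std of a user-designated noise window, overridable. Contrast
ratios use user-supplied or segmentation-derived foreground/background
masks; a zero background mean returns +inf rather than raising.

## Resolution estimation

The erf-edge fit `a/2·(1+erf((x−x₀)/(σ√2)))+b` is solved by
Levenberg–Marquardt with x₀ initialized at the steepest-gradient sample,
σ at ¼ of the 10–90 % rise distance, and a, b from tail medians; tests
check it against an exhaustive (σ, x₀) grid search with the linear
parameters solved exactly. FWHM is reported as 2.355σ — the constant as
conventionally printed — with the full-precision 2·√(2 ln 2) available as
an option. Note that a fitted σ of 4.25–4.4 gives FWHM 10.0–10.4 in the
same units, slightly above a nominal 9–10 µm lateral resolution if σ is
read in µm; the package reports both σ and FWHM and leaves the unit
interpretation to the caller (edge profiles may be supplied in pixels or
µm and results carry the input unit). Envelope FWHM uses linear
interpolation of the half-maximum crossings. Pulse-echo sound speed is
the closed form `v = 2d/Δt`.

## Overlay

PCHIP (shape-preserving Hermite, continuous first derivative, no
overshoot on monotone data) builds all lookup and alpha tables;
`scipy.interpolate.PchipInterpolator` provides the interpolant, wrapped
with strict duplicate-knot and extrapolation errors, and tests verify it
against an explicit Hermite-basis evaluation with independently
recomputed monotone slopes. Defaults: SAM = gray ramp, PAM = the hot ramp
reversed ("inverted hot", so the combined 512-row matrix is gray in its
first half and inverted hot in its second), LUT length 256 per modality
matching the 8-bit histogram convention, alpha ramps 0→1. The
"combined by multiplication" step is ambiguous between index arithmetic
and intensity products, so both are implemented: source-over alpha
compositing (default `blend`, physically interpretable) and the literal
`index_product` that multiplies the normalized intensities and indexes
the combined matrix. Angular views rotate the voxel grid
(nearest-neighbour, default 30°/30°) and re-project, which is
deterministic and dependency-light; it is not a ray-cast volume
rendering.

## Pipeline

One YAML config drives the chain; the top-level seed overrides the
phantom seed. `report.json` is fully deterministic under a fixed
(config, seed) — the config hash excludes the output directory, and
wall-clock stage timings are written to a separate `timings.json` sidecar
precisely so they cannot perturb the report. Provenance (config hash) is
recorded in the report and the HDF5 description; image artifacts carry no
embedded metadata.

## Problem sizes and what the tests show

Tests and the acceptance script use small rasters (single A-lines up to
60×60 grids) with the full-resolution 400 MHz time axis, which exercises
every code path at realistic depth sampling while keeping the suite fast.
Passing tests demonstrate internal consistency and correct parameter
recovery under the forward model's own assumptions — first-order
reflections, plane layers, Gaussian pulses, white noise. They do not
demonstrate robustness to real-tissue effects the generator omits:
speckle from sub-resolution scatterers, frequency-dependent attenuation,
phase aberration through curved interfaces, transducer focal-zone
geometry, or laser pulse-energy jitter. The sound-speed recovery, for
example, is accurate to ≪1 % on the phantom because both echoes are clean;
on real data the same estimator inherits the uncertainty of picking echo
peaks in clutter.
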