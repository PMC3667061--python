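# Methods

## The measurement problem

Fura-2 is a ratiometric Ca²⁺ indicator: emission excited at 340 nm rises
and at 380 nm falls as calcium binds, so the 340:380 ratio tracks
intracellular calcium independently of dye loading and illumination. A
two-filter acquisition alternates exposures through the two filters
(≈0.8 frames/s per channel with a mechanical filter wheel); a mechanical
stimulus at a known frame launches a radially propagating intercellular
wave. The package estimates the wave's source, mean front velocity,
amplitude and decay from such sequences. We work directly with the
computed ratio rather than converting to absolute [Ca²⁺] — conversion
requires an in-situ calibration that is orthogonal to wave
characterization.

## Calibration model

**Registration.** Motion between frames is modelled as a rigid integer
translation. Because the two channels have different intensity mappings,
frames are first reduced to a single starlet (isotropic à trous,
B3-spline kernel `[1,4,6,4,1]/16`) detail layer holding 1 px or 2 px
structure, max–min rescaled to [0, 1]; the translation is then the peak
of the Fourier phase-correlation surface against the first frame of the
sequence. Shifts are undone by whole pixels with edge replication; no
sub-pixel or affine model is attempted since observed misalignments are a
few pixels of rigid drift. The à trous smoothing uses reflect boundaries;
the telescoping identity (sum of details + final smooth = input) holds
exactly regardless.

**Ratio.** One ratio frame per consecutive (340, 380) pair,
`R = I₃₄₀/(I₃₈₀ + ε)` with ε = 10⁻⁶ of full scale guarding empty pixels.
The ratio frame inherits the 340 nm frame's time; same-channel frame i is
at `t = i·Δt` with t = 0 at acquisition start.

**Marker-decay correction.** Each wavelength bleaches with its own
e-folding time, so the ratio acquires a spurious exponential trend even
though each channel's bleaching is individually benign. We fit
`flux(t) = a·exp(−t/τ_b) + c` (least squares, a ≥ 0, τ_b > 0, offset
free) to the per-frame total ratio flux over pre-stimulus frames only —
post-stimulus frames contain signal and the fluorescence does not return
to basal within the sequence, so they never enter the fit — and divide
each frame by `flux(t)/flux(0)`. The correction is multiplicative
(flux-ratio normalization) since the bias enters the ratio as a
multiplicative factor. If the optimizer fails, a log-linear fit with zero
offset is used and flagged. Extrapolation quality is the main noise
sensitivity of the whole pipeline: with only 10 basal frames a 2%
intensity noise level leaves a few-percent systematic tilt in the
corrected sequence, which shrinks quickly with more basal frames (30–50
are recommended and used in the recovery checks; real acquisitions
routinely capture that many).

**Basal image and wave extraction.** The basal ratio image is the
per-pixel mean of pre-stimulus frames after one sigma-reject pass:
values with `|x − mean| ≥ 2·std` (per pixel, across frames) are
discarded and the mean recomputed; if everything is rejected the plain
mean is kept. Rejection is strict-inequality — a single gross outlier
among n otherwise identical values sits at exactly 2σ of its series and
must be discarded — and single-pass, not iterated. The wave stack is
`w_t = median_k(max(R_t − basal, 0))` with a k×k median (k ∈ {1,3,5},
default 3): subtraction isolates released calcium, truncation reflects
that negative excess is noise, and the small median suppresses the noise
amplification inherent to ratios of noisy images while preserving
pixel-scale structure. Per-pixel statistics (maximum, time of maximum
with ties resolved to the earliest frame, mean, standard deviation) are
computed on the filtered stack.

## Signal mask

Threshold the per-pixel maximum image at `median + 1·std` (the median
operationalizes the "background level" robustly against the bright wave
region), then apply binary closing and opening with disc structuring
elements (default both 7 px diameter, order and sizes configurable —
different orders genuinely give different masks and the choice is left to
inspection). Optionally the mask is clipped to a maximum radius about the
source, since SNR falls with distance. An empty mask is returned with a
warning, and the pipeline then falls back to unmasked analysis; with a
nearly-uniform bright max image (wave filling most of the frame) the
automatic threshold is known to overshoot — set `mask_threshold`
explicitly in that case.

## Global analysis

**Source.** The wave-onset frame is grayscale-opened (3×3 erosion then
dilation), rescaled to [0,1], thresholded at 0.2, and the
intensity-weighted center of mass is refined by iteratively halving the
window (re-centered on the running center of mass, clamped to the frame)
until the next window would drop below 20 px per side. This converges to
the biggest, brightest structure and ignores secondary releases. The
pipeline applies it to the wave frame a few frames (default 3) past the
stimulus: at the stimulus instant the synthetic release is a single
pixel, which the 3×3 opening would erase, while a few frames later it is
a cell-sized blob — the situation real data presents from the start.
Manual coordinates may always be supplied instead.

**Ring reduction.** Pixels are binned by `r ≤ dist < r+1` (Euclidean, in
pixels, about the source) and averaged per ring and frame, giving a
radius × time map. One-pixel rings maximize radial resolution without
mixing distances; the binning partitions the disc exactly, so
`Σ_r mean_r·count_r` equals the disc sum. Empty rings are NaN and skipped.

**Velocities.** Per ring, the front time is the time of the maximum value
(`max_intensity`) or of the maximum positive forward difference
`v[t+1]−v[t]` (`max_gradient`; the forward first difference is the
simplest estimator of "maximum increase", and argmax ties resolve to the
earliest time). A sigma-clipped iterated OLS (clip at 2σ of residuals,
≤5 passes, with a numerically-exact-fit early exit) of time on radius
gives velocity = 1/slope in px/s, converted to µm/s by the pixel size
(default 1.025 µm/px, the documented acquisition scale). Non-positive
slopes are flagged and the velocity reported undefined. Dispersion of
activation times grows with radius in real tissue, delaying the intensity
maximum more than the front; gradient-derived velocities therefore sit at
or above intensity-derived ones, and the generator's
`activation_dispersion` option (one-sided exponential delays with scale
∝ r) reproduces that ordering.

**Maximum propagation radius.** Per-ring maxima beyond `r_min`
(default 10 px, excluding the near-source region) are fitted by the same
robust line; the zero crossing `−intercept/slope` estimates where the
wave dies out. A non-negative slope, or a crossing beyond 10× the
measured radial range, is reported as undefined rather than extrapolated.

**Decay models.** Ring (and pixel) time series are fitted with
three-parameter Heaviside-gated decays — exponential
`H(t−t₀)·A·e^−(t−t₀)/τ` and rational-quadratic
`H(t−t₀)·A·τ²/(τ²+(t−t₀)²)`, with H(0) = 1 — by bounded damped
Gauss–Newton least squares (`scipy.optimize.least_squares`, TRF; the
same Levenberg–Marquardt family as MINPACK, with bounds A ≥ 0, τ > 0, t₀
inside the acquisition span added for robustness on noisy pixels).
Initialization: t₀ at the time of maximum forward difference, A at the
series maximum, τ at a quarter of the post-t₀ span; a couple of t₀
restarts shifted by ±½ and +1½ sample guard against the gate's piecewise
cost surface. For the exponential model the gate leaves t₀ identified
only up to the sampling interval — shifting t₀ to the next sample time
while rescaling A by `e^(−δ/τ)` predicts identical values at every sample
— so fits are canonicalized to the ridge point t₀ = first sample with
predicted activation. This is deterministic, changes no residual, and is
exact whenever the true onset lies on the acquisition grid. All-zero
series return an A = 0 fit flagged non-converged.

**Activation velocity.** t₀ regressed on radius over converged ring fits
(failed rings are dropped) gives a third velocity estimate, 1/slope.

## Local analysis

The same fit runs independently at every mask-on pixel (order cannot
matter), initialized from the calibration statistics (A at the pixel
maximum, t₀ at its time of maximum) — those statistics approximate the
fit well and cut iterations substantially. Non-processed and
non-converged pixels keep sentinel 0 in all maps so they render black;
residuals are recorded regardless. Maps stay in seconds. No spatial
regularization is applied.

## One-filter mode

Velocity-only analysis from the 380 nm stream at up to 2.8 frames/s
(no second exposure, no filter-wheel rotation). The calibration is
identical minus the ratio step, with the sign inverted —
`w = median(max(basal − I₃₈₀, 0))` — because 380 nm emission falls as
calcium binds. Marker-decay correction is applied to the single channel
by the same flux-flattening (toggleable). Only the maximum-gradient
velocity is offered: the 380 nm intensity maximum correlates poorly with
the calcium maximum, so `max_intensity` requests raise an error. On
matched synthetic experiments the one- and two-filter gradient velocities
agree within the temporal quantization bound of the coarser sequence
(worst-case OLS slope perturbation 3·Δt/R for timing errors ≤ Δt over a
radial span R, i.e. |Δv| ≤ 3·v²·Δt/R).

## Synthetic experiments

The generator emulates the acquisition the pipeline assumes: inside a
disc footprint about the source, the true ratio is
`basal + f(t; A, t₀, τ)` with `t₀ = t_stim + dist/velocity`; channel
intensities are constructed so the computed ratio is exact
(`I₃₈₀ = base·(1 − k·f/(basal+f))·e^(−t/τ₃₈₀)`,
`I₃₄₀ = (basal+f)·I₃₈₀-without-decay·e^(−t/τ₃₄₀)`), each channel
bleaches with its own e-folding time, frames can be circularly shifted
per frame, and Gaussian noise is added per channel before clipping to
[0, 1]. A static smoothed-noise texture (20% amplitude, ≈1.5 px
correlation) stands in for cell structure so registration has features to
lock onto. Defaults, chosen once as representative acquisition
conditions: basal ratio 1.0; base 380 nm intensity 0.4 of full scale;
dip fraction k = 0.5; bleach e-folds 250 s (340 nm) / 400 s (380 nm) —
the faster 340 nm bleach makes the ratio-flux trend a decaying
exponential, the case the correction model represents exactly; noise
σ = 0.5% of full scale; frame period 1.25 s two-filter, 1/2.8 s
single-filter; A = 0.5, τ = 20 s, velocity 5 px/s, footprint 30% of the
frame side. A and τ can taper linearly with radius, and activation
dispersion (above) emulates cell-to-cell release delays.

`radial_quantize=True` switches to lockstep-annulus activation
(`t₀ = t_stim + floor(dist)/velocity`): every pixel of a one-pixel ring
shares one onset, and with `velocity·Δt = 1 px/frame` those onsets fall
exactly on acquisition instants. This is the reference condition under
which ring averaging introduces no onset smearing and per-ring parameter
recovery is exact to optimizer precision; it deliberately relaxes the
continuous `t₀ = dist/velocity` law, which is retained everywhere else.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: cell geometry and intercellular
delays (beyond the statistical dispersion option), diffusion physics,
spontaneous secondary releases, photon shot noise (noise is additive
Gaussian, not intensity-dependent), non-rigid motion, and out-of-focus
background.

## Numerical choices and degenerate inputs

- Ratio guard ε = 10⁻⁶ full scale; division never yields NaN/Inf.
- Constant images: starlet detail layer is all zeros (returned, not
  raised); featureless registration inputs return (0, 0) with a warning;
  a constant stimulus image raises a no-source error.
- Median-filter kernel must be odd and ≤ 5; mask disc diameters odd in
  [3, 15].
- Sigma-clip of the robust line stops when the residual std is
  numerically zero (≤10⁻¹² of the data scale) to avoid clipping on
  floating-point jitter; rejection is monotone (a dropped point stays
  dropped) and at least 3 points are always kept.
- Decay-fit tolerances: xtol = ftol = gtol = 10⁻¹² (per-series fits),
  10⁻¹⁴ for the flux fit, which is extrapolated and needs the extra
  accuracy.
- Misalignment is circular (wrap-around) in the generator — the
  phase-correlation model — while correction uses edge replication;
  interior pixels are restored exactly.

## Problem sizes used in the checks

Recovery and acceptance checks run on 64–192 px frames, 18–70 radial
bins, 40–150 frames, and 60–100 random seeds; per-pixel fits are
exercised on a 128×128 × 100-frame stack (≈7,800 masked fits). These
sizes keep full-suite runs in minutes while leaving every estimator's
operating regime (multi-step quantization, ring counts from 1 to ~400
pixels, noise levels 0–2%) represented.

## Known limitations

- Velocity quantization: with Δt = 1.25 s a 10 px/s wave advances
  12.5 px per frame; radial spans ≳ 5 steps (≥60 px) are needed for
  percent-level velocity recovery. Faster waves want the one-filter mode
  or larger fields.
- t₀ is reported at frame resolution (the canonical ridge point); its
  sub-frame position is unidentifiable from gated-exponential samples.
- The automatic mask threshold assumes the wave occupies a minority of
  the frame; otherwise it overshoots and the pipeline falls back to
  unmasked analysis (or take manual control of the threshold).
- The marker-decay correction extrapolates a fit from pre-stimulus frames
  across the whole sequence; short basal captures leave percent-level
  tilts under noise.
- Decay-correction of the one-filter stream assumes the same exponential
  bleaching model holds for the single channel.
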