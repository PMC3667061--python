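# cawave — calibration and velocimetry of propagating Ca²⁺ waves

Mechanically stimulating a ciliated epithelial cell releases calcium that
spreads to its neighbours as a radial intercellular wave; the wave's
velocity, amplitude and decay characterize signalling in the tissue.
`cawave` turns raw two-filter Fura-2 fluorescence sequences (interlaced
340 nm / 380 nm exposures, one 8/16-bit grayscale TIFF per frame) into
those quantities, automatically and reproducibly:

1. **Calibration** — rigid integer-pixel registration by Fourier phase
   correlation on a starlet (isotropic à trous) wavelet detail layer;
   per-pair 340/380 ratio (the Fura-2 ratio indexes [Ca²⁺]ᵢ);
   marker-decay correction by fitting `a·exp(−t/τ_b) + c` to the
   pre-stimulus total flux and flattening the extrapolated trend;
   sigma-reject (2σ) averaging of pre-stimulus frames into a basal image;
   wave extraction `w = median₃ₓ₃(max(R − basal, 0))` plus per-pixel
   maximum, time-of-maximum, mean and standard deviation maps.
2. **Signal masking** — threshold at one standard deviation over the
   background level of the maximum map, cleaned by binary closing/opening
   with disc structuring elements (5–9 px).
3. **Global analysis** — automatic source localization (grayscale
   opening, 0.2 threshold, iteratively halving center of mass); reduction
   to a radius × time map by one-pixel-wide concentric ring averages;
   wave-front velocity `v = 1/slope` from sigma-clipped regressions of
   front time on radius (front time = time of maximum intensity, or of
   maximum positive temporal gradient); maximum propagation radius from a
   linear decay fit of per-ring maxima; and per-ring least-squares fits of
   the Heaviside-gated decay models

   ```
   exponential:  f(t) = H(t − t₀) · A · e^(−(t − t₀)/τ)
   quadratic:    f(t) = H(t − t₀) · A · τ² / (τ² + (t − t₀)²)
   ```

   whose activation times t₀, regressed on radius, give an independent
   velocity estimate.
4. **Local analysis** — the same three-parameter fit at every masked
   pixel, producing A / t₀ / τ maps.
5. **One-filter mode** — velocity-only analysis of a 380 nm stream at a
   higher frame rate (the wave appears as an intensity *decrease*);
   only the maximum-gradient estimator is allowed there.

A synthetic-experiment generator (`cawave.synthgen`) produces physically
matched sequences with known ground truth (source, velocity, per-pixel
A/t₀/τ, channel bleach times, misalignments, noise), so every stage is
tested by parameter recovery — no microscope data is required.

## Worked example

```python
import cawave as cw

truth = cw.make_truth((192, 192), velocity=5.0, footprint_radius=78,
                      noise_sigma=0.0, amplitude_taper="linear")
seq, _ = cw.generate_experiment((192, 192), n_frames=40, frame_period=1.25,
                                truth=truth, seed=42)
res = cw.CalciumWaveAnalysis(seq, max_radius=70, use_mask=False).fit()
print(res.summary())
```

```
Calcium wave analysis
==========================================================
source (row, col)         : (95, 95)  [auto]
frame period              : 1.25 s
pixel size                : 1.025 um/px
radial bins used          : 70
velocity (max gradient)   : 5.035 px/s = 5.160 um/s  (R^2=0.992, n=70, rejected=0)
velocity (max intensity)  : 4.979 px/s = 5.104 um/s  (R^2=0.992, n=70, rejected=0)
velocity (activation t0)  : 5.035 px/s = 5.160 um/s  (R^2=0.992, n=70, rejected=0)
max propagation radius    : 155.4 px = 159.3 um
mean decay rate tau       : 20.70 s  (model: exponential, 70 rings)
```

The generated wave propagated at 5 px/s from pixel (96, 96) with τ = 20 s
and an amplitude tapering linearly to half at radius 78 (hence zero at
156): all three velocity estimators land within ~1%, the extrapolated
maximum propagation radius within 1 px, and the mean fitted decay rate
within 4%. `res.ring_table()` holds the per-radius (A, t₀, τ) fits;
`res.plot_radial_map()` shows the radius × time reduction.

The same pipeline runs from the shell:

```bash
cawave simulate --out data --shape 192,192 --n-frames 40 --velocity 5 --seed 42
cawave analyze --input data --stimulus-frame 10 --max-radius 70 --out results
```

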