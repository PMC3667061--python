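"""Image calibration and wave extraction.

Turns a raw interlaced 340/380 nm sequence into a registered,
decay-corrected, basal-subtracted non-negative wave stack with per-pixel
statistics:

1. rigid integer-pixel registration by Fourier phase correlation, after a
   starlet (isotropic a trous B3-spline) wavelet prefilter that keeps only
   pixel-scale structure so both excitation channels become comparable;
2. per-pair 340/380 ratio, indexing intracellular Ca2+;
3. correction of the fluorophore's natural decay: the two wavelengths
   bleach at different rates, biasing the ratio, so an exponential is
   fitted to the pre-stimulus total flux and extrapolated forward;
4. sigma-reject averaging of pre-stimulus frames into a basal image;
5. basal subtraction, truncation to non-negative values, median filtering,
   and per-pixel statistics (maximum, time of maximum, mean, std).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .exceptions import (
    DecayCorrectionError,
    InsufficientDataError,
    ParameterError,
)
from .io_seq import CH_340, CH_380, CH_RATIO, FrameSequence

__all__ = [
    "starlet_decompose",
    "starlet_prefilter",
    "register_translation",
    "apply_shift",
    "register_sequence",
    "compute_ratio",
    "fit_marker_decay",
    "correct_marker_decay",
    "estimate_basal",
    "extract_wave",
    "calibrate",
    "DecayFit",
    "WaveStats",
    "CalibratedWave",
]

RATIO_EPS = 1e-6  # guard added to the 380 nm denominator, in full-scale units

# B3-spline scaling kernel of the starlet transform
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_smooth(image: np.ndarray, level: int) -> np.ndarray:
    """One a-trous smoothing step: B3 kernel with 2**level - 1 holes."""
    kernel = np.zeros(4 * 2**level + 1)
    kernel[:: 2**level] = _B3
    out = ndimage.convolve1d(image, kernel, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel, axis=1, mode="reflect")


def starlet_decompose(image: np.ndarray, n_scales: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Starlet (undecimated isotropic wavelet) decomposition.

    Returns ``(details, smooth)`` where ``details[j]`` holds structure of
    characteristic size ~2**j pixels and the sum of all details plus the
    final smooth plane reconstructs the input exactly.
    """
    c = np.asarray(image, dtype=np.float64)
    details = []
    for j in range(n_scales):
        c_next = _atrous_smooth(c, j)
        details.append(c - c_next)
        c = c_next
    return details, c


def starlet_prefilter(image: np.ndarray, keep_scale: int = 1) -> np.ndarray:
    """Keep one starlet detail layer and max-min rescale it to [0, 1].

    keep_scale selects the layer of 1 px or 2 px structures. A constant
    image (or any degenerate rescale) returns an all-zero grid rather than
    raising.
    """
    if keep_scale not in (1, 2):
        raise ParameterError("keep_scale must be 1 or 2")
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ParameterError("image must be finite")
    details, _ = starlet_decompose(image, keep_scale)
    layer = details[keep_scale - 1]
    lo, hi = layer.min(), layer.max()
    if hi - lo <= 0:
        return np.zeros_like(layer)
    return (layer - lo) / (hi - lo)


def register_translation(
    reference: np.ndarray, target: np.ndarray, keep_scale: int = 1
) -> tuple[int, int]:
    """Integer (dy, dx) displacement of ``target`` relative to ``reference``.

    Both images are starlet-prefiltered, then the peak of the Fourier
    phase-correlation surface gives the translation: if
    ``target == roll(reference, (dy, dx))`` the return value is (dy, dx),
    and applying the negated shift to ``target`` aligns it. All-zero
    prefiltered input yields (0, 0) with a warning.
    """
    if reference.shape != target.shape:
        raise ParameterError("reference and target must share a shape")
    ref_f = starlet_prefilter(reference, keep_scale)
    tgt_f = starlet_prefilter(target, keep_scale)
    if not ref_f.any() or not tgt_f.any():
        warnings.warn("featureless image: registration falls back to zero shift")
        return (0, 0)
    shift, _, _ = phase_cross_correlation(ref_f, tgt_f, upsample_factor=1, normalization="phase")
    # phase_cross_correlation returns the shift moving target onto reference
    return (-int(round(shift[0])), -int(round(shift[1])))


def apply_shift(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate by whole pixels, replicating edge rows/cols."""
    dy, dx = int(shift[0]), int(shift[1])
    return ndimage.shift(np.asarray(image, dtype=np.float64), (dy, dx), order=0, mode="nearest")


def register_sequence(
    seq: FrameSequence, keep_scale: int = 1
) -> tuple[FrameSequence, list[tuple[int, int]]]:
    """Align every frame to the first frame of the sequence.

    Returns the aligned sequence and the per-frame estimated (dy, dx)
    displacements of the raw frames.
    """
    ref = seq.frames[0]
    shifts = [(0, 0)]
    aligned = [np.asarray(ref, dtype=np.float64)]
    for frame in seq.frames[1:]:
        s = register_translation(ref, frame, keep_scale)
        shifts.append(s)
        aligned.append(apply_shift(frame, (-s[0], -s[1])))
    return seq.with_frames(np.stack(aligned)), shifts


def compute_ratio(seq: FrameSequence, eps: float = RATIO_EPS) -> FrameSequence:
    """340/380 ratio of consecutive frame pairs.

    One ratio frame per (340, 380) pair; the ratio frame takes the 340 nm
    frame's acquisition time. An odd trailing frame is dropped with a
    warning; negative intensities are rejected.
    """
    labels = seq.channel_labels
    if set(labels) != {CH_340, CH_380}:
        raise ParameterError("compute_ratio requires an alternating 340/380 sequence")
    frames = seq.frames
    if len(frames) % 2:
        warnings.warn("odd trailing frame dropped before ratio computation")
        frames = frames[:-1]
    if np.any(frames < 0):
        raise ParameterError("negative intensities are not valid raw data")
    num = np.asarray(frames[0::2], dtype=np.float64)
    den = np.asarray(frames[1::2], dtype=np.float64)
    ratio = num / (den + eps)
    return FrameSequence(
        frames=ratio,
        channel_labels=[CH_RATIO] * len(ratio),
        frame_period=seq.frame_period,
        stimulus_frame=seq.stimulus_frame,
        pixel_size=seq.pixel_size,
    )


@dataclass
class DecayFit:
    """Exponential fit amplitude*exp(-t/efold_time) + offset to the total flux."""

    amplitude: float
    efold_time: float
    offset: float
    fitted_range: tuple[int, int]
    fallback: bool = False

    def flux(self, t):
        return self.amplitude * np.exp(-np.asarray(t, dtype=np.float64) / self.efold_time) + self.offset


def fit_marker_decay(ratio_seq: FrameSequence, stimulus_frame: int | None = None) -> DecayFit:
    """Fit the marker-decay exponential to pre-stimulus total flux.

    The per-frame total flux (sum of all pixels of each ratio frame) over
    the frames before the stimulus is fitted by least squares with
    ``flux(t) = amplitude * exp(-t / efold_time) + offset``. Only
    pre-stimulus frames enter the fit; the function is extrapolated to the
    rest of the sequence by :func:`correct_marker_decay`.
    """
    if stimulus_frame is None:
        stimulus_frame = ratio_seq.stimulus_frame
    if stimulus_frame < 4:
        raise InsufficientDataError("marker-decay fit needs at least 4 pre-stimulus frames")
    flux = np.asarray(
        [f.sum(dtype=np.float64) for f in ratio_seq.frames[:stimulus_frame]], dtype=np.float64
    )
    t = np.arange(stimulus_frame) * ratio_seq.frame_period
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    tau_hi = 1e9 * span

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    a0 = max(flux[0] - flux[-1], 1e-12)
    p0 = (a0, span / 2.0, flux[-1])
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            flux,
            p0=p0,
            bounds=([0.0, 1e-9, -np.inf], [np.inf, tau_hi, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
        return DecayFit(popt[0], popt[1], popt[2], (0, stimulus_frame))
    except RuntimeError:
        # log-linear fallback with zero offset
        safe = np.clip(flux, 1e-300, None)
        slope, intercept = np.polyfit(t, np.log(safe), 1)
        efold = min(-1.0 / slope, tau_hi) if slope < 0 else tau_hi
        return DecayFit(np.exp(intercept), efold, 0.0, (0, stimulus_frame), fallback=True)


def correct_marker_decay(ratio_seq: FrameSequence, fit: DecayFit) -> FrameSequence:
    """Flatten the fitted flux trend: frame at time t is scaled by flux(0)/flux(t)."""
    t = ratio_seq.times()
    flux_t = fit.flux(t)
    if np.any(flux_t <= 0):
        raise DecayCorrectionError("fitted flux is non-positive inside the sequence span")
    factors = fit.flux(0.0) / flux_t
    corrected = np.asarray(ratio_seq.frames, dtype=np.float64) * factors[:, None, None]
    return ratio_seq.with_frames(corrected)


def estimate_basal(
    ratio_seq: FrameSequence, stimulus_frame: int | None = None, sigma: float = 2.0
) -> np.ndarray:
    """Sigma-reject mean of the pre-stimulus ratio frames.

    Per pixel, values outside ``mean +/- sigma*std`` across the pre-stimulus
    frames are discarded in a single rejection pass, then the mean is
    recomputed over the survivors. A pixel whose values are all rejected
    falls back to its unclipped mean.
    """
    if stimulus_frame is None:
        stimulus_frame = ratio_seq.stimulus_frame
    stack = np.asarray(ratio_seq.frames[:stimulus_frame], dtype=np.float64)
    if len(stack) == 0:
        raise InsufficientDataError("no pre-stimulus frames")
    if len(stack) == 1:
        warnings.warn("single basal frame: returned as-is, no rejection possible")
        return stack[0].copy()
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    # strict inequality: a value at exactly sigma*std is discarded (a single
    # gross outlier among n identical values always lands exactly there)
    keep = np.abs(stack - mean) < sigma * std
    n_keep = keep.sum(axis=0)
    clipped_sum = np.where(keep, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        clipped_mean = clipped_sum / n_keep
    return np.where(n_keep > 0, clipped_mean, mean)


@dataclass
class WaveStats:
    """Per-pixel statistics of the wave stack."""

    maximum: np.ndarray
    time_of_maximum: np.ndarray  # seconds; earliest frame on ties
    mean: np.ndarray
    std: np.ndarray

    def as_dict(self) -> dict:
        return {
            "maximum": self.maximum,
            "time_of_maximum": self.time_of_maximum,
            "mean": self.mean,
            "std": self.std,
        }


@dataclass
class CalibratedWave:
    """Decay-corrected, basal-subtracted, non-negative wave stack."""

    wave: np.ndarray  # (time, rows, cols), >= 0
    basal: np.ndarray
    stats: WaveStats
    decay_fit: DecayFit | None
    shifts: list[tuple[int, int]] = field(default_factory=list)
    frame_period: float = 1.0
    pixel_size: float = 1.025
    stimulus_frame: int = 0

    @property
    def shape(self):
        return self.wave.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(len(self.wave)) * self.frame_period


def _wave_stats(wave: np.ndarray, frame_period: float) -> WaveStats:
    maximum = wave.max(axis=0)
    time_of_max = wave.argmax(axis=0) * frame_period  # argmax takes the earliest tie
    return WaveStats(maximum, time_of_max.astype(np.float64), wave.mean(axis=0), wave.std(axis=0))


def extract_wave(
    ratio_seq: FrameSequence, basal: np.ndarray, median_kernel: int = 3
) -> CalibratedWave:
    """Subtract the basal image, truncate to >= 0, median filter, and score.

    ``wave[i] = median_filter(max(ratio[i] - basal, 0))`` with a square
    kernel of odd size <= 5. Statistics (per-pixel maximum, time of
    maximum in seconds, mean, standard deviation) are computed on the
    filtered stack.
    """
    if median_kernel not in (1, 3, 5):
        raise ParameterError("median_kernel must be odd and <= 5")
    basal = np.asarray(basal, dtype=np.float64)
    if basal.shape != ratio_seq.shape:
        raise ParameterError("basal shape does not match the frames")
    excess = np.clip(np.asarray(ratio_seq.frames, dtype=np.float64) - basal, 0.0, None)
    if median_kernel > 1:
        wave = np.stack([ndimage.median_filter(f, size=median_kernel) for f in excess])
    else:
        wave = excess
    return CalibratedWave(
        wave=wave,
        basal=basal,
        stats=_wave_stats(wave, ratio_seq.frame_period),
        decay_fit=None,
        frame_period=ratio_seq.frame_period,
        pixel_size=ratio_seq.pixel_size,
        stimulus_frame=ratio_seq.stimulus_frame,
    )


def calibrate(
    seq: FrameSequence,
    keep_scale: int = 1,
    sigma: float = 2.0,
    median_kernel: int = 3,
    register: bool = True,
    decay_correct: bool = True,
) -> CalibratedWave:
    """Full two-filter calibration: register, ratio, decay-correct, basal, wave."""
    shifts: list[tuple[int, int]] = []
    if register:
        seq, shifts = register_sequence(seq, keep_scale)
    ratio = compute_ratio(seq)
    decay_fit = None
    if decay_correct:
        decay_fit = fit_marker_decay(ratio)
        ratio = correct_marker_decay(ratio, decay_fit)
    basal = estimate_basal(ratio, sigma=sigma)
    wave = extract_wave(ratio, basal, median_kernel)
    wave.decay_fit = decay_fit
    wave.shifts = shifts
    return wave
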