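"""Global analysis of the calibrated wave under radial symmetry.

The wave stack is reduced to a (time x radial distance) map by averaging
concentric one-pixel-wide rings around the propagation source. From that
map come:

* mean wave-front velocities, from robust linear regressions of the time
  of maximum intensity (or of maximum positive temporal gradient) against
  radius — velocity is the reciprocal slope, reported in px/s and um/s;
* the maximum propagation radius, extrapolated from a linear decay fit of
  the per-ring maximum intensity far from the stimulus;
* per-ring parametric decay fits of the Heaviside-gated models

      exponential:  f(t) = H(t - t0) * A * exp(-(t - t0)/tau)
      quadratic:    f(t) = H(t - t0) * A * tau^2 / (tau^2 + (t - t0)^2)

  whose activation times t0, regressed against radius, give an
  independent velocity estimate.

The source itself is localized automatically from the stimulus-frame
image by grayscale opening, thresholding at 0.2 of the normalized range,
and an iteratively halving center-of-mass search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    NoSourceError,
    ParameterError,
)

__all__ = [
    "find_source",
    "ring_profile",
    "robust_linear_fit",
    "velocity_fit",
    "amplitude_decay_fit",
    "evaluate_model",
    "fit_decay_model",
    "fit_rings",
    "activation_velocity",
    "RadialTimeMap",
    "LinearFit",
    "WaveModelParams",
]


# --------------------------------------------------------------------------
# source localization


def find_source(stimulus_image: np.ndarray, min_window: int = 20) -> tuple[int, int]:
    """Locate the propagation source in the stimulus-frame image.

    The image is opened with 3x3 grayscale erosion+dilation, linearly
    rescaled to [0, 1], and values below 0.2 are zeroed. The
    intensity-weighted center of mass is then refined by successive
    halving: each iteration halves the computation window per dimension,
    recentered on the current center of mass, until the next window would
    fall below ``min_window`` pixels in either dimension. This converges
    to the center of the biggest, brightest structure, ignoring secondary
    releases; on failure the caller may supply manual coordinates.
    """
    img = np.asarray(stimulus_image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ParameterError("image must be finite")
    opened = ndimage.grey_dilation(ndimage.grey_erosion(img, size=3), size=3)
    lo, hi = opened.min(), opened.max()
    if hi - lo <= 0:
        raise NoSourceError("constant image: no structure to localize")
    norm = (opened - lo) / (hi - lo)
    norm[norm < 0.2] = 0.0
    if not norm.any():
        raise NoSourceError("image empty after thresholding")

    rows, cols = norm.shape

    def com(r0, r1, c0, c1):
        sub = norm[r0:r1, c0:c1]
        total = sub.sum()
        if total <= 0:
            return None
        rr = np.arange(r0, r1, dtype=np.float64)
        cc = np.arange(c0, c1, dtype=np.float64)
        return (sub.sum(axis=1) @ rr) / total, (sub.sum(axis=0) @ cc) / total

    window = (0, rows, 0, cols)
    center = com(*window)
    if center is None:
        raise NoSourceError("image empty after thresholding")
    h, w = rows, cols
    while True:
        nh, nw = h // 2, w // 2
        if nh < min_window or nw < min_window:
            break
        r0 = int(round(center[0] - nh / 2))
        c0 = int(round(center[1] - nw / 2))
        r0 = min(max(r0, 0), rows - nh)
        c0 = min(max(c0, 0), cols - nw)
        new_center = com(r0, r0 + nh, c0, c0 + nw)
        if new_center is None:
            break
        center = new_center
        h, w = nh, nw
    return (int(round(center[0])), int(round(center[1])))


# --------------------------------------------------------------------------
# radial reduction


@dataclass
class RadialTimeMap:
    """Ring-averaged intensity indexed by (time, radial distance).

    ``values[t, r]`` is the mean wave intensity over the pixels whose
    Euclidean distance d to the source satisfies r <= d < r+1 (half-open
    one-pixel rings); NaN marks empty rings.
    """

    values: np.ndarray  # (n_times, n_radii)
    counts: np.ndarray  # pixels per ring
    source: tuple[int, int]
    frame_period: float
    pixel_size: float = 1.025

    @property
    def n_radii(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.frame_period

    def valid_radii(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)


def ring_profile(
    wave: np.ndarray,
    source: tuple[int, int],
    max_radius: int,
    mask: np.ndarray | None = None,
    frame_period: float = 1.0,
    pixel_size: float = 1.025,
) -> RadialTimeMap:
    """Average the wave stack over concentric one-pixel-wide rings."""
    wave = np.asarray(wave, dtype=np.float64)
    n_t, rows, cols = wave.shape
    sr, sc = source
    if not (0 <= sr < rows and 0 <= sc < cols):
        raise ParameterError("source must lie inside the frame")
    if max_radius < 2:
        raise ParameterError("max_radius must be >= 2")
    limit = int(np.ceil(np.hypot(max(sr, rows - 1 - sr), max(sc, cols - 1 - sc))))
    if max_radius > limit:
        warnings.warn(f"max_radius {max_radius} clipped to frame bound {limit}")
        max_radius = limit

    rr, cc = np.ogrid[:rows, :cols]
    dist = np.hypot(rr - sr, cc - sc)
    ring = np.floor(dist).astype(np.intp)
    valid = ring < max_radius
    if mask is not None:
        m = mask.mask if hasattr(mask, "mask") else np.asarray(mask)
        valid &= m.astype(bool)
    idx = ring[valid]
    counts = np.bincount(idx, minlength=max_radius).astype(np.intp)
    values = np.empty((n_t, max_radius), dtype=np.float64)
    for t in range(n_t):
        sums = np.bincount(idx, weights=wave[t][valid], minlength=max_radius)
        with np.errstate(invalid="ignore"):
            values[t] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialTimeMap(values, counts, (sr, sc), frame_period, pixel_size)


# --------------------------------------------------------------------------
# linear fits


@dataclass
class LinearFit:
    """Sigma-clipped least-squares line, interpretable as a velocity.

    For the velocity modes the regression is time (y) on radius (x), so
    the mean propagation velocity is ``1/slope`` in px/s.
    """

    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_rejected: int
    mode: str = "generic"
    pixel_size: float | None = None
    flag: str | None = None

    @property
    def velocity_px_s(self) -> float | None:
        if self.mode not in ("max_intensity", "max_gradient", "activation_time"):
            return None
        if self.slope <= 0:
            return None
        return 1.0 / self.slope

    @property
    def velocity_um_s(self) -> float | None:
        v = self.velocity_px_s
        if v is None or self.pixel_size is None:
            return None
        return v * self.pixel_size


def robust_linear_fit(
    x, y, clip_sigma: float = 2.0, max_iter: int = 5, mode: str = "generic"
) -> LinearFit:
    """Ordinary least squares with iterated sigma-clipping of residuals.

    Fit, compute the residual standard deviation, drop points with
    ``|residual| > clip_sigma * std``, refit; stop at convergence or after
    ``max_iter`` passes. R^2, n_used and n_rejected describe the final fit.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size or x.size < 3:
        raise DegenerateFitError("robust fit needs >= 3 (x, y) points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all x values identical")
    keep = np.ones(x.size, dtype=bool)
    slope = intercept = 0.0
    for _ in range(max_iter):
        xs, ys = x[keep], y[keep]
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = y - (slope * x + intercept)
        std = resid[keep].std()
        if std <= 1e-12 * max(1.0, float(np.abs(y[keep]).max())):
            break  # (numerically) perfect fit: nothing left to clip
        new_keep = np.abs(resid) <= clip_sigma * std
        new_keep &= keep  # rejection is monotone: once out, stays out
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    xs, ys = x[keep], y[keep]
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=max(0.0, min(1.0, r2)),
        n_used=int(keep.sum()),
        n_rejected=int(x.size - keep.sum()),
        mode=mode,
    )


def _front_times(rt_map: RadialTimeMap, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-ring wave-front time: argmax of value or of its forward difference."""
    valid = rt_map.valid_radii()
    if valid.size < 3:
        raise InsufficientDataError("need >= 3 valid radial bins")
    vals = rt_map.values[:, valid]
    if mode == "max_intensity":
        t_idx = np.argmax(vals, axis=0)
    elif mode == "max_gradient":
        if vals.shape[0] < 2:
            raise InsufficientDataError("max_gradient needs >= 2 time samples")
        t_idx = np.argmax(np.diff(vals, axis=0), axis=0)
    else:
        raise ParameterError(f"unknown velocity mode {mode!r}")
    return valid.astype(np.float64), t_idx * rt_map.frame_period


def velocity_fit(
    rt_map: RadialTimeMap, mode: str = "max_gradient", clip_sigma: float = 2.0
) -> LinearFit:
    """Mean propagation velocity from the radial-time map.

    Per radial bin the wave-front time is the time of the maximum value
    (``max_intensity``) or of the maximum positive forward temporal
    difference (``max_gradient``); a robust regression of time on radius
    gives velocity = 1/slope. A non-positive slope is flagged non-physical
    and the velocity is reported as undefined (None).
    """
    radii, times = _front_times(rt_map, mode)
    fit = robust_linear_fit(radii, times, clip_sigma=clip_sigma, mode=mode)
    fit.pixel_size = rt_map.pixel_size
    if fit.slope <= 0:
        fit.flag = "non-physical slope; velocity undefined"
    return fit


def amplitude_decay_fit(
    rt_map: RadialTimeMap, r_min: int = 10, clip_sigma: float = 2.0
) -> tuple[LinearFit, float | None]:
    """Linear decay of per-ring maximum intensity beyond ``r_min``.

    Far from the stimulus the maximum reached intensity falls roughly
    linearly with radius; extrapolating the fitted line to zero gives the
    maximum propagation radius. Returns ``(fit, zero_crossing_radius)``;
    the crossing is None (flagged) when the slope is non-negative.
    """
    valid = rt_map.valid_radii()
    valid = valid[valid >= r_min]
    if valid.size < 3:
        raise InsufficientDataError("need >= 3 radial bins beyond r_min")
    maxima = np.nanmax(rt_map.values[:, valid], axis=0)
    fit = robust_linear_fit(valid.astype(float), maxima, clip_sigma=clip_sigma, mode="amplitude_decay")
    fit.pixel_size = rt_map.pixel_size
    # a slope indistinguishable from zero (vs. the data scale) is non-decaying
    tiny = max(1e-12, 1e-9 * np.ptp(maxima) / max(np.ptp(valid), 1))
    crossing = None
    if fit.slope < -tiny:
        crossing = -fit.intercept / fit.slope
        if crossing > 10.0 * rt_map.n_radii:
            # so shallow a decay that the extrapolation is meaningless
            crossing = None
            fit.flag = "amplitude decay too shallow to extrapolate"
    else:
        fit.flag = "non-decaying amplitude; maximum radius undefined"
    return fit, crossing


# --------------------------------------------------------------------------
# decay models


@dataclass
class WaveModelParams:
    """Parameters (A, t0, tau) of the Heaviside-gated decay models."""

    A: float
    t0: float
    tau: float
    model_kind: str = "exponential"
    residual_norm: float = 0.0
    converged: bool = True


def evaluate_model(p: WaveModelParams, t) -> np.ndarray:
    """Evaluate the decay model at time(s) t; H(0) = 1 (wave present at onset)."""
    t = np.asarray(t, dtype=np.float64)
    dt = t - p.t0
    gate = dt >= 0
    if p.model_kind == "exponential":
        with np.errstate(over="ignore"):
            out = p.A * np.exp(-np.where(gate, dt, 0.0) / p.tau)
    elif p.model_kind == "quadratic":
        out = p.A * p.tau**2 / (p.tau**2 + dt**2)
    else:
        raise ParameterError(f"unknown model_kind {p.model_kind!r}")
    return np.where(gate, out, 0.0)


def _model_residuals(theta, t, y, model_kind):
    a, t0, tau = theta
    return (
        evaluate_model(WaveModelParams(a, t0, tau, model_kind), t) - y
    )


def fit_decay_model(
    times,
    values,
    model_kind: str = "exponential",
    init: WaveModelParams | None = None,
) -> WaveModelParams:
    """Levenberg-Marquardt-style least-squares fit of (A, t0, tau).

    Unless ``init`` is given, t0 starts at the time of the maximum forward
    difference, A at the series maximum and tau at a quarter of the
    post-t0 span. Because the Heaviside gate makes the cost piecewise
    smooth in t0, a couple of shifted t0 restarts guard against landing in
    the wrong inter-sample interval; the best iterate is kept. All-zero
    series return an A=0 fit flagged as non-converged.
    """
    t = np.asarray(times, dtype=np.float64).ravel()
    y = np.asarray(values, dtype=np.float64).ravel()
    if t.size != y.size or t.size < 6:
        raise InsufficientDataError("decay fit needs >= 6 time points")
    if np.any(y < 0):
        raise ParameterError("series must be non-negative")
    if model_kind not in ("exponential", "quadratic"):
        raise ParameterError(f"unknown model_kind {model_kind!r}")
    if not y.any():
        return WaveModelParams(0.0, t[0], 1.0, model_kind, 0.0, converged=False)

    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    span = t[-1] - t[0]
    y_scale = float(y.max())

    if init is not None:
        starts = [(max(init.A, 1e-12), init.t0, max(init.tau, 1e-6))]
        # one nudge earlier in case the init sits past the true onset
        starts.append((max(init.A, 1e-12), init.t0 - 0.5 * dt, max(init.tau, 1e-6)))
    else:
        t_g = t[int(np.argmax(np.diff(y)))] if y.size > 1 else t[0]
        a0 = y_scale
        tau0 = max((t[-1] - t_g) / 4.0, dt / 2.0, 1e-6)
        starts = [
            (a0, t_g + 0.5 * dt, tau0),
            (a0, t_g - 0.5 * dt, tau0),
            (a0, t_g + 1.5 * dt, tau0),
        ]

    lower = [0.0, t[0] - 2.0 * dt, 1e-9]
    upper = [np.inf, t[-1], 100.0 * max(span, dt)]
    best = None
    for a0, t00, tau0 in starts:
        t00 = min(max(t00, lower[1]), upper[1])
        tau0 = min(max(tau0, lower[2]), upper[2])
        try:
            res = optimize.least_squares(
                _model_residuals,
                x0=[a0, t00, tau0],
                bounds=(lower, upper),
                args=(t, y, model_kind),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= (1e-12 * y_scale) ** 2 * t.size:
            break
    if best is None:
        return WaveModelParams(0.0, t[0], 1.0, model_kind, float(np.linalg.norm(y)), converged=False)
    a, t0, tau = best.x
    if model_kind == "exponential":
        # The Heaviside gate leaves t0 identified only up to the sampling
        # interval: shifting t0 to the next sample while rescaling A by
        # exp(-(t0' - t0)/tau) predicts identical values at every sample.
        # Canonicalize to the ridge point t0 = first sample with predicted
        # activation, which is deterministic and exact for on-grid onsets.
        idx = int(np.searchsorted(t, t0 - 1e-9 * max(dt, 1.0)))
        if idx < t.size and t[idx] > t0:
            a *= np.exp(-(t[idx] - t0) / tau)
            t0 = t[idx]
    resid = float(np.sqrt(2.0 * best.cost))
    converged = bool(best.status > 0)
    return WaveModelParams(float(a), float(t0), float(tau), model_kind, resid, converged)


def fit_rings(
    rt_map: RadialTimeMap,
    model_kind: str = "exponential",
    min_amplitude: float = 0.0,
) -> list[tuple[int, WaveModelParams]]:
    """Fit the decay model to every valid ring's time series.

    Rings whose series never exceeds ``min_amplitude`` or whose fit fails
    to converge are dropped from the result (and hence from downstream
    regressions).
    """
    t = rt_map.times()
    out = []
    for r in rt_map.valid_radii():
        y = rt_map.values[:, r]
        if not np.isfinite(y).all() or y.max() <= min_amplitude:
            continue
        p = fit_decay_model(t, np.clip(y, 0.0, None), model_kind)
        if p.converged and p.A > 0:
            out.append((int(r), p))
    return out


def activation_velocity(
    params_by_radius: list[tuple[int, WaveModelParams]],
    clip_sigma: float = 2.0,
    pixel_size: float | None = None,
) -> LinearFit:
    """Velocity from the regression of fitted activation time on radius."""
    pts = [(r, p.t0) for r, p in params_by_radius if p.converged]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 converged per-radius fits")
    r, t0 = zip(*pts)
    fit = robust_linear_fit(r, t0, clip_sigma=clip_sigma, mode="activation_time")
    fit.pixel_size = pixel_size
    if fit.slope <= 0:
        fit.flag = "non-physical slope; velocity undefined"
    return fit
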