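"""Model/results interface tying the pipeline stages together.

`CalciumWaveAnalysis` is constructed from a raw :class:`FrameSequence`
(two-filter interlaced, or a single 380 nm stream) plus the analysis
choices; ``fit()`` runs calibration, optional masking, source
localization, radial reduction, the linear velocity fits, the per-ring
decay-model fits, and (optionally) the per-pixel fits, and returns a
:class:`WaveAnalysisResults` carrying every estimate with diagnostics, a
``summary()`` table and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, global_analysis, local_analysis, masking, one_filter
from .exceptions import CaWaveError, ParameterError
from .io_seq import CH_340, CH_380, FrameSequence

__all__ = ["CalciumWaveAnalysis", "WaveAnalysisResults"]


@dataclass
class WaveAnalysisResults:
    """Estimates and diagnostics of a fitted calcium-wave analysis."""

    calibrated: object
    mask: masking.SignalMask | None
    source: tuple[int, int]
    source_auto: bool
    radial_map: global_analysis.RadialTimeMap
    intensity_fit: global_analysis.LinearFit | None
    gradient_fit: global_analysis.LinearFit
    amplitude_fit: global_analysis.LinearFit | None = None
    max_propagation_radius: float | None = None
    ring_params: list = field(default_factory=list)
    activation_fit: global_analysis.LinearFit | None = None
    local_maps: local_analysis.ParameterMaps | None = None
    model_kind: str = "exponential"
    single_filter: bool = False
    config: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    @property
    def velocity_gradient(self) -> float | None:
        """Wave-front velocity from the maximum-gradient regression (px/s)."""
        return self.gradient_fit.velocity_px_s

    @property
    def velocity_intensity(self) -> float | None:
        return self.intensity_fit.velocity_px_s if self.intensity_fit else None

    @property
    def velocity_activation(self) -> float | None:
        return self.activation_fit.velocity_px_s if self.activation_fit else None

    @property
    def mean_decay_rate(self) -> float | None:
        """Mean fitted decay rate tau (s) over the converged rings."""
        taus = [p.tau for _, p in self.ring_params if p.converged]
        return float(np.mean(taus)) if taus else None

    def ring_table(self) -> pd.DataFrame:
        """Per-radius fit table: r, A, t0, tau, residual."""
        rows = [
            {"r_px": r, "A": p.A, "t0_s": p.t0, "tau_s": p.tau, "residual": p.residual_norm}
            for r, p in self.ring_params
        ]
        return pd.DataFrame(rows, columns=["r_px", "A", "t0_s", "tau_s", "residual"])

    def summary(self) -> str:
        """Human-readable report of the fitted wave characteristics."""
        px = self.radial_map.pixel_size
        lines = [
            "Calcium wave analysis" + ("  [single filter]" if self.single_filter else ""),
            "=" * 58,
            f"source (row, col)         : {self.source}"
            + ("  [auto]" if self.source_auto else "  [manual]"),
            f"frame period              : {self.radial_map.frame_period:.4g} s",
            f"pixel size                : {px:.4g} um/px",
            f"radial bins used          : {len(self.radial_map.valid_radii())}",
        ]
        if self.mask is not None:
            lines.append(f"mask area                 : {self.mask.area} px")

        def vline(name, fit):
            if fit is None:
                return f"{name:<26}: (not computed)"
            v = fit.velocity_px_s
            if v is None:
                return f"{name:<26}: undefined ({fit.flag})"
            return (
                f"{name:<26}: {v:.3f} px/s = {v * px:.3f} um/s"
                f"  (R^2={fit.r_squared:.3f}, n={fit.n_used}, rejected={fit.n_rejected})"
            )

        lines.append(vline("velocity (max gradient)", self.gradient_fit))
        lines.append(vline("velocity (max intensity)", self.intensity_fit))
        lines.append(vline("velocity (activation t0)", self.activation_fit))
        if self.max_propagation_radius is not None:
            lines.append(
                f"max propagation radius    : {self.max_propagation_radius:.1f} px"
                f" = {self.max_propagation_radius * px:.1f} um"
            )
        if self.mean_decay_rate is not None:
            lines.append(
                f"mean decay rate tau       : {self.mean_decay_rate:.2f} s"
                f"  (model: {self.model_kind}, {len(self.ring_params)} rings)"
            )
        if self.local_maps is not None:
            lines.append(
                f"local fits converged      : {self.local_maps.n_converged} px"
            )
        return "\n".join(lines)

    def plot_radial_map(self, ax=None):
        """Radial distance vs time map (the ring-sample image)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            self.radial_map.values,
            aspect="auto",
            origin="upper",
            extent=(0, self.radial_map.n_radii, self.radial_map.times()[-1], 0),
        )
        ax.set_xlabel("radial distance (px)")
        ax.set_ylabel("time (s)")
        ax.figure.colorbar(im, ax=ax, label="mean ratio excess")
        return ax

    def plot_velocity_fit(self, mode: str = "max_gradient", ax=None):
        """Front time vs radius with the fitted regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        radii, times = global_analysis._front_times(self.radial_map, mode)
        fit = self.gradient_fit if mode == "max_gradient" else self.intensity_fit
        ax.plot(radii, times, ".", label="ring front times")
        if fit is not None:
            xs = np.array([radii.min(), radii.max()])
            ax.plot(xs, fit.slope * xs + fit.intercept, "-", label=f"fit (R^2={fit.r_squared:.2f})")
        ax.set_xlabel("radius (px)")
        ax.set_ylabel("time (s)")
        ax.legend()
        return ax


class CalciumWaveAnalysis:
    """End-to-end analysis of one calcium-wave experiment.

    Parameters
    ----------
    seq : FrameSequence
        Raw interlaced 340/380 sequence (or 380-only stream with
        ``single_filter=True``).
    source : "auto" or (row, col)
        Propagation source; "auto" localizes it from the wave frame
        ``source_frame_offset`` frames after the stimulus.
    max_radius : int, optional
        Outer radius (px) of the ring reduction; default reaches the
        nearest frame edge.
    use_mask : bool
        Build a signal mask from the statistics and fit over masked data
        (recommended).
    fit_local : bool
        Also run the per-pixel fits (slowest stage).
    """

    def __init__(
        self,
        seq: FrameSequence,
        source="auto",
        max_radius: int | None = None,
        model_kind: str = "exponential",
        use_mask: bool = True,
        fit_local: bool = False,
        single_filter: bool = False,
        median_kernel: int = 3,
        sigma: float = 2.0,
        keep_scale: int = 1,
        register: bool = True,
        decay_correct: bool = True,
        r_min: int = 10,
        source_frame_offset: int = 3,
        mask_ops=masking.DEFAULT_OPS,
        mask_threshold: float | None = None,
    ):
        if single_filter and set(seq.channel_labels) == {CH_340, CH_380}:
            raise ParameterError("single_filter=True but the sequence is two-filter interlaced")
        self.seq = seq
        self.source = source
        self.max_radius = max_radius
        self.model_kind = model_kind
        self.use_mask = use_mask
        self.fit_local = fit_local
        self.single_filter = single_filter
        self.median_kernel = median_kernel
        self.sigma = sigma
        self.keep_scale = keep_scale
        self.register = register
        self.decay_correct = decay_correct
        self.r_min = r_min
        self.source_frame_offset = source_frame_offset
        self.mask_ops = mask_ops
        self.mask_threshold = mask_threshold

    def _config(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "source",
                "max_radius",
                "model_kind",
                "use_mask",
                "fit_local",
                "single_filter",
                "median_kernel",
                "sigma",
                "keep_scale",
                "register",
                "decay_correct",
                "r_min",
                "source_frame_offset",
            )
        }

    def fit(self) -> WaveAnalysisResults:
        seq = self.seq
        if self.single_filter:
            cal = one_filter.extract_wave_single(
                seq,
                sigma=self.sigma,
                median_kernel=self.median_kernel,
                register=self.register,
                decay_correct=self.decay_correct,
                keep_scale=self.keep_scale,
            )
        else:
            cal = calibration.calibrate(
                seq,
                keep_scale=self.keep_scale,
                sigma=self.sigma,
                median_kernel=self.median_kernel,
                register=self.register,
                decay_correct=self.decay_correct,
            )

        # source localization on an early post-stimulus wave frame
        source_auto = self.source == "auto"
        if source_auto:
            idx = min(cal.stimulus_frame + self.source_frame_offset, len(cal.wave) - 1)
            src = global_analysis.find_source(cal.wave[idx])
        else:
            src = (int(self.source[0]), int(self.source[1]))

        mask = None
        if self.use_mask:
            mask = masking.build_mask(
                cal.stats,
                threshold=self.mask_threshold,
                morph_ops=self.mask_ops,
                max_radius=self.max_radius,
                source=src,
            )
            if mask.empty:
                mask = None  # fall back to unmasked analysis

        rows, cols = cal.wave.shape[1:]
        max_radius = self.max_radius
        if max_radius is None:
            max_radius = int(min(src[0], rows - 1 - src[0], src[1], cols - 1 - src[1]))
            max_radius = max(max_radius, 2)

        rt_map = global_analysis.ring_profile(
            cal.wave,
            src,
            max_radius,
            mask=mask,
            frame_period=cal.frame_period,
            pixel_size=cal.pixel_size,
        )

        gradient_fit = global_analysis.velocity_fit(rt_map, mode="max_gradient")
        intensity_fit = None
        amplitude_fit = None
        crossing = None
        ring_params: list = []
        activation_fit = None
        if not self.single_filter:
            intensity_fit = global_analysis.velocity_fit(rt_map, mode="max_intensity")
            try:
                amplitude_fit, crossing = global_analysis.amplitude_decay_fit(rt_map, self.r_min)
            except CaWaveError:
                pass
            ring_params = global_analysis.fit_rings(rt_map, self.model_kind)
            try:
                activation_fit = global_analysis.activation_velocity(
                    ring_params, pixel_size=cal.pixel_size
                )
            except CaWaveError:
                pass

        local_maps = None
        if self.fit_local and not self.single_filter:
            local_maps = local_analysis.fit_pixelwise(cal, mask, self.model_kind)

        return WaveAnalysisResults(
            calibrated=cal,
            mask=mask,
            source=src,
            source_auto=source_auto,
            radial_map=rt_map,
            intensity_fit=intensity_fit,
            gradient_fit=gradient_fit,
            amplitude_fit=amplitude_fit,
            max_propagation_radius=crossing,
            ring_params=ring_params,
            activation_fit=activation_fit,
            local_maps=local_maps,
            model_kind=self.model_kind,
            single_filter=self.single_filter,
            config=self._config(),
        )
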