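"""Reading raw interlaced frame sequences and writing calibrated outputs.

Raw data arrives as one grayscale TIFF per frame (8- or 16-bit), interlaced
340 nm / 380 nm for the two-filter mode or a single 380 nm stream.  Frames
are rescaled to fractions of full scale and held as 32-bit floats.  Outputs
(wave stacks, basal images, per-pixel statistics) are written as 32-bit
floating-point FITS to preserve numerical accuracy, with a plain-text
manifest mapping names to files.

Conventions used by every module downstream: pixel coordinates are 0-based
(row, col); radial distances are Euclidean in pixel units; the time of
same-channel frame i is ``i * frame_period`` seconds with t=0 at the first
frame, and a ratio frame inherits its 340 nm frame's time.
"""

from __future__ import annotations

import glob as _glob
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from ._fits import ImageHDU, read_fits, write_fits
from .exceptions import ChannelLabelError, ParameterError, ShapeError

__all__ = ["FrameSequence", "read_sequence", "write_sequence", "write_outputs", "read_output"]

CH_340 = "340"
CH_380 = "380"
CH_RATIO = "ratio"
CH_SINGLE = "single"


@dataclass
class FrameSequence:
    """A time-ordered stack of single-channel frames with timing metadata.

    Attributes
    ----------
    frames : ndarray, shape (n, rows, cols), float32
        Intensities as fractions of full scale (0..1 for raw data).
    channel_labels : list of str
        Per-frame tag in {"340", "380", "ratio", "single"}.
    frame_period : float
        Seconds between consecutive same-channel exposures.
    stimulus_frame : int
        Index (same-channel numbering) of the first post-stimulus frame.
    pixel_size : float
        Microns per pixel.
    """

    frames: np.ndarray
    channel_labels: list[str]
    frame_period: float
    stimulus_frame: int
    pixel_size: float = 1.025

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ShapeError("frames must be a (n, rows, cols) stack")
        if len(self.channel_labels) != len(self.frames):
            raise ChannelLabelError("one channel label per frame is required")
        if self.frame_period <= 0:
            raise ParameterError("frame_period must be > 0")
        labels = set(self.channel_labels)
        if labels == {CH_340, CH_380}:
            expect = [CH_340, CH_380] * (len(self.frames) // 2 + 1)
            if self.channel_labels != expect[: len(self.frames)]:
                raise ChannelLabelError("two-filter channels must strictly alternate 340/380")
            n_pairs = len(self.frames) // 2
        else:
            n_pairs = len(self.frames)
        if not 0 <= self.stimulus_frame < max(n_pairs, 1):
            raise ParameterError(
                f"stimulus_frame {self.stimulus_frame} outside the same-channel frame range"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        """Acquisition time (s) of each same-channel frame."""
        labels = set(self.channel_labels)
        n = self.n_frames // 2 if labels == {CH_340, CH_380} else self.n_frames
        return np.arange(n) * self.frame_period

    def channel(self, label: str) -> np.ndarray:
        """Stack of all frames carrying the given channel label."""
        idx = [i for i, lab in enumerate(self.channel_labels) if lab == label]
        if not idx:
            raise ChannelLabelError(f"no frames labeled {label!r}")
        return self.frames[idx]

    def with_frames(self, frames: np.ndarray) -> "FrameSequence":
        return replace(self, frames=np.asarray(frames, dtype=np.float32))


def _label_from_name(name: str) -> str | None:
    base = os.path.basename(name)
    has340, has380 = "340" in base, "380" in base
    if has340 and not has380:
        return CH_340
    if has380 and not has340:
        return CH_380
    return None


def read_sequence(
    path_or_pattern,
    channel_rule: str = "token",
    frame_period: float = 1.25,
    stimulus_frame: int = 10,
    pixel_size: float = 1.025,
) -> FrameSequence:
    """Load a numbered TIFF sequence into a :class:`FrameSequence`.

    Parameters
    ----------
    path_or_pattern : str or path or list of paths
        A directory (all ``.tif``/``.tiff`` files, sorted), a glob pattern,
        or an explicit list of files in acquisition order.
    channel_rule : {"token", "even_odd", "single"}
        "token": filenames containing "340"/"380" decide the channel.
        "even_odd": even-indexed frames are 340 nm, odd are 380 nm.
        "single": one-filter 380 nm stream.

    Frames are rescaled to [0, 1] by the container full-scale value
    (255 for 8-bit, 65535 for 16-bit).
    """
    if isinstance(path_or_pattern, (list, tuple)):
        files = [str(p) for p in path_or_pattern]
    else:
        p = str(path_or_pattern)
        if os.path.isdir(p):
            files = sorted(
                _glob.glob(os.path.join(p, "*.tif")) + _glob.glob(os.path.join(p, "*.tiff"))
            )
        else:
            files = sorted(_glob.glob(p))
    if not files:
        raise FileNotFoundError(f"no frames match {path_or_pattern!r}")

    frames, labels = [], []
    shape = None
    for i, f in enumerate(files):
        img = tifffile.imread(f)
        if img.ndim != 2:
            raise ShapeError(f"{f}: expected a single grayscale frame, got shape {img.shape}")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ShapeError(f"{f}: shape {img.shape} differs from first frame {shape}")
        if img.dtype == np.uint8:
            scale = 255.0
        elif img.dtype == np.uint16:
            scale = 65535.0
        elif np.issubdtype(img.dtype, np.floating):
            scale = 1.0
        else:
            raise ParameterError(f"{f}: unsupported dtype {img.dtype}")
        frames.append(np.asarray(img, dtype=np.float32) / scale)
        if channel_rule == "token":
            lab = _label_from_name(f)
            if lab is None:
                raise ChannelLabelError(f"cannot resolve channel of {f!r} from filename tokens")
        elif channel_rule == "even_odd":
            lab = CH_340 if i % 2 == 0 else CH_380
        elif channel_rule == "single":
            lab = CH_SINGLE
        else:
            raise ParameterError(f"unknown channel_rule {channel_rule!r}")
        labels.append(lab)

    return FrameSequence(
        frames=np.stack(frames),
        channel_labels=labels,
        frame_period=frame_period,
        stimulus_frame=stimulus_frame,
        pixel_size=pixel_size,
    )


def write_sequence(seq: FrameSequence, out_dir, bit_depth: int = 8) -> list[str]:
    """Write a sequence as numbered single-frame grayscale TIFFs.

    Filenames encode the acquisition index and channel
    (``frame_0001_340.tif``) so the default ``token`` rule reads them back.
    """
    if bit_depth == 8:
        scale, dtype = 255.0, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535.0, np.uint16
    else:
        raise ParameterError("bit_depth must be 8 or 16")
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, (frame, lab) in enumerate(zip(seq.frames, seq.channel_labels)):
        tag = lab if lab in (CH_340, CH_380) else "380"
        name = f"frame_{i:04d}_{tag}.tif"
        path = os.path.join(out_dir, name)
        data = np.clip(np.round(np.clip(frame, 0.0, 1.0) * scale), 0, scale).astype(dtype)
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def write_outputs(images: dict, out_dir, manifest_name: str = "manifest.txt") -> dict:
    """Save named 2-D/3-D grids as 32-bit float FITS files plus a manifest.

    Returns the manifest as a dict name -> file path. Writing an empty dict
    yields an empty manifest and no error.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for name, grid in images.items():
        fname = f"{name}.fits"
        path = os.path.join(out_dir, fname)
        try:
            write_fits(path, np.asarray(grid))
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        manifest[name] = fname
    with open(os.path.join(out_dir, manifest_name), "w") as fh:
        for name, fname in manifest.items():
            fh.write(f"{name}\t{fname}\n")
    return manifest


def read_output(path) -> np.ndarray:
    """Read back a grid written by :func:`write_outputs`."""
    return np.asarray(read_fits(path)[0].data)
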