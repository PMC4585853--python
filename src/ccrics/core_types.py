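"""Shared domain types: acquisition geometry, image stacks, ROI windows.

Conventions used throughout the package:

* coordinates are 0-based and row-major;
* the fast scan axis is the column axis (lag symbol ``xi``), the slow axis
  is the row axis (lag symbol ``psi``);
* within a frame the pixel at (row, col) is acquired at
  ``t = row * line_time + col * pixel_dwell``; frame ``f`` starts at
  ``f * frame_interval``;
* lengths are micrometres, times are seconds.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import tifffile

__all__ = [
    "GeometryError",
    "StackValidationError",
    "AcquisitionGeometry",
    "ImageStack",
    "ROIWindow",
    "validate_stack_pair",
    "default_geometry",
    "read_tiff_stack",
    "read_dual_tiff",
    "write_tiff_stack",
]

CHANNEL_GREEN = "green"
CHANNEL_RED = "red"


class GeometryError(ValueError):
    """Raised when acquisition geometry violates its invariants."""


class StackValidationError(ValueError):
    """Raised when an image stack (or stack pair) violates its invariants."""


_GEOMETRY_CONFIG_KEYS = {
    "pixel_size_um",
    "pixel_dwell_us",
    "line_time_us",
    "w0_um",
    "wz_um",
    "gamma",
}


@dataclasses.dataclass(frozen=True)
class AcquisitionGeometry:
    """Raster-scan timing and optical geometry.

    Parameters
    ----------
    pixel_size:
        Pixel size ``delta_r`` in micrometres per pixel.
    pixel_dwell:
        Pixel dwell time ``tau_p`` in seconds.
    line_time:
        Line time ``tau_l`` in seconds; must cover all pixel dwells of a
        line (``line_time >= n_cols * pixel_dwell``), any excess is flyback.
    waist_lateral, waist_axial:
        Lateral (``w0``) and axial (``wz``) 1/e^2 radii of the focal
        volume, micrometres.
    n_rows, n_cols:
        Image dimensions in pixels.
    gamma:
        Geometric correction factor for a 3D Gaussian observation volume.
    """

    pixel_size: float
    pixel_dwell: float
    line_time: float
    waist_lateral: float
    waist_axial: float
    n_rows: int
    n_cols: int
    gamma: float = 0.35

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise GeometryError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.pixel_dwell > 0):
            raise GeometryError(f"pixel_dwell must be > 0, got {self.pixel_dwell}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("n_rows and n_cols must be >= 1")
        min_line = self.n_cols * self.pixel_dwell
        if self.line_time < min_line * (1 - 1e-12):
            raise GeometryError(
                f"line_time {self.line_time:g} s is shorter than "
                f"n_cols * pixel_dwell = {min_line:g} s"
            )
        if not (self.waist_lateral > 0):
            raise GeometryError("waist_lateral must be > 0")
        if self.waist_axial < self.waist_lateral:
            raise GeometryError(
                f"waist_axial ({self.waist_axial}) must be >= waist_lateral "
                f"({self.waist_lateral})"
            )
        if not (0 < self.gamma <= 1):
            raise GeometryError(f"gamma must be in (0, 1], got {self.gamma}")

    @property
    def frame_duration(self) -> float:
        """Time to scan all lines of one frame (no inter-frame gap)."""
        return self.n_rows * self.line_time

    @property
    def flyback_time(self) -> float:
        """Dead time per line after the last pixel dwell."""
        return self.line_time - self.n_cols * self.pixel_dwell

    @property
    def effective_volume(self) -> float:
        """Effective observation volume ``pi^(3/2) w0^2 wz`` (um^3)."""
        return math.pi ** 1.5 * self.waist_lateral**2 * self.waist_axial

    def pixel_time(self, row, col):
        """Within-frame acquisition time of pixel (row, col)."""
        return np.asarray(row) * self.line_time + np.asarray(col) * self.pixel_dwell

    def pixel_times(self) -> np.ndarray:
        """Within-frame acquisition times on the full pixel lattice.

        Returns a flat array of length ``n_rows * n_cols`` in scan order.
        """
        rows, cols = np.divmod(np.arange(self.n_rows * self.n_cols), self.n_cols)
        return rows * self.line_time + cols * self.pixel_dwell

    @classmethod
    def from_config(cls, cfg: dict, n_rows: int, n_cols: int) -> "AcquisitionGeometry":
        """Build from a config block with micrometre/microsecond keys.

        Expected keys: ``pixel_size_um``, ``pixel_dwell_us``, ``line_time_us``,
        ``w0_um``, ``wz_um`` and optional ``gamma``. Unknown keys are rejected.
        """
        unknown = set(cfg) - _GEOMETRY_CONFIG_KEYS
        if unknown:
            raise GeometryError(f"unknown geometry config keys: {sorted(unknown)}")
        missing = (_GEOMETRY_CONFIG_KEYS - {"gamma"}) - set(cfg)
        if missing:
            raise GeometryError(f"missing geometry config keys: {sorted(missing)}")
        return cls(
            pixel_size=float(cfg["pixel_size_um"]),
            pixel_dwell=float(cfg["pixel_dwell_us"]) * 1e-6,
            line_time=float(cfg["line_time_us"]) * 1e-6,
            waist_lateral=float(cfg["w0_um"]),
            waist_axial=float(cfg["wz_um"]),
            n_rows=n_rows,
            n_cols=n_cols,
            gamma=float(cfg.get("gamma", 0.35)),
        )

    def to_config(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size,
            "pixel_dwell_us": self.pixel_dwell * 1e6,
            "line_time_us": self.line_time * 1e6,
            "w0_um": self.waist_lateral,
            "wz_um": self.waist_axial,
            "gamma": self.gamma,
        }


def default_geometry(n_rows: int, n_cols: int, **overrides) -> AcquisitionGeometry:
    """Pipeline-default geometry: 22 nm pixels, 12.8 us dwell, no flyback,
    w0 = 0.2 um, wz = 1.0 um, gamma = 0.35."""
    params = dict(
        pixel_size=0.022,
        pixel_dwell=12.8e-6,
        waist_lateral=0.2,
        waist_axial=1.0,
        gamma=0.35,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    params.update(overrides)
    params.setdefault("line_time", n_cols * params["pixel_dwell"])
    return AcquisitionGeometry(**params)


@dataclasses.dataclass
class ImageStack:
    """A single-channel time series of raster-scanned frames.

    ``data`` is indexed (frame, row, col); raw values must be finite and
    non-negative (photon-count-like). ``frame_interval`` is the time between
    successive frame starts in seconds.  Detrended stacks (``detrended=True``)
    hold floating fluctuation values and may dip below zero.
    """

    data: np.ndarray
    channel_label: str
    frame_interval: float
    detrended: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StackValidationError(
                f"stack data must be 3D (frame, row, col); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise StackValidationError(
                f"stack '{self.channel_label}' contains non-finite values"
            )
        if not self.detrended and np.any(self.data < 0):
            raise StackValidationError(
                f"stack '{self.channel_label}' contains negative values"
            )
        if self.frame_interval <= 0:
            raise StackValidationError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, detrended: bool | None = None) -> "ImageStack":
        if detrended is None:
            detrended = self.detrended
        return ImageStack(data, self.channel_label, self.frame_interval, detrended)


@dataclasses.dataclass(frozen=True)
class ROIWindow:
    """Rectangular pixel window, 0-based inclusive start, exclusive end."""

    row_start: int
    col_start: int
    height: int
    width: int

    MIN_SIDE = 8  # fits need at least this many lags

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI start indices must be >= 0")
        if self.height < self.MIN_SIDE or self.width < self.MIN_SIDE:
            raise ValueError(
                f"ROI sides must be >= {self.MIN_SIDE}px, got "
                f"{self.height}x{self.width}"
            )

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_start + self.height),
            slice(self.col_start, self.col_start + self.width),
        )

    def clipped(self, image_shape: tuple[int, int]) -> "ROIWindow":
        """Truncate the window to the image bounds."""
        n_rows, n_cols = image_shape
        if self.row_start >= n_rows or self.col_start >= n_cols:
            raise ValueError("ROI start lies outside the image")
        return ROIWindow(
            self.row_start,
            self.col_start,
            min(self.height, n_rows - self.row_start),
            min(self.width, n_cols - self.col_start),
        )

    def contains(self, image_shape: tuple[int, int]) -> bool:
        n_rows, n_cols = image_shape
        return (
            self.row_start + self.height <= n_rows
            and self.col_start + self.width <= n_cols
        )


def validate_stack_pair(green: ImageStack, red: ImageStack) -> tuple[ImageStack, ImageStack]:
    """Check that two channel stacks are jointly analyzable.

    Raises :class:`StackValidationError` naming the offending axis on
    frame-count or frame-shape mismatch (value invariants are enforced by
    :class:`ImageStack` itself).
    """
    if green.n_frames != red.n_frames:
        raise StackValidationError(
            f"frame-count mismatch on axis 0: green has {green.n_frames}, "
            f"red has {red.n_frames}"
        )
    if green.frame_shape != red.frame_shape:
        raise StackValidationError(
            f"frame-shape mismatch on axes (1, 2): green {green.frame_shape} "
            f"vs red {red.frame_shape}"
        )
    return green, red


# ---------------------------------------------------------------------------
# TIFF I/O


def write_tiff_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per frame."""
    tifffile.imwrite(str(path), stack.data)


def read_tiff_stack(path, channel_label: str, frame_interval: float) -> ImageStack:
    """Read a multi-page single-channel TIFF as an :class:`ImageStack`."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackValidationError(
            f"{path}: expected 2D/3D single-channel TIFF, got shape {data.shape}"
        )
    return ImageStack(data, channel_label, frame_interval)


def read_dual_tiff(path, frame_interval: float) -> tuple[ImageStack, ImageStack]:
    """Read a 2-sample-per-pixel dual-channel TIFF and split the channels.

    Accepts page shapes (rows, cols, 2) or a (frames, 2, rows, cols) axis
    layout; channel 0 is taken as green, channel 1 as red.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise StackValidationError(f"{path}: expected dual-channel TIFF, got shape {data.shape}")
    if data.shape[-1] == 2:
        g, r = data[..., 0], data[..., 1]
    elif data.shape[1] == 2:
        g, r = data[:, 0], data[:, 1]
    else:
        raise StackValidationError(
            f"{path}: no 2-sample channel axis in shape {data.shape}"
        )
    return (
        ImageStack(g, CHANNEL_GREEN, frame_interval),
        ImageStack(r, CHANNEL_RED, frame_interval),
    )
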