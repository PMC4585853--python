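"""Detrending and 2D spatial auto-/cross-correlation of image stacks.

The correlation estimator is the standard fluctuation form

    G(xi, psi) = <dI_a(x, y) * dI_b(x + xi, y + psi)> / (<I_a> <I_b>)

with fluctuations ``dI`` taken about the per-frame spatial mean, computed as
a *linear* (zero-padded, non-circular) correlation via FFT and normalized at
every lag by the number of overlapping pixel pairs.  Surfaces are computed
per frame and then averaged over frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .core_types import ImageStack, ROIWindow

__all__ = [
    "KIND_ACF_GREEN",
    "KIND_ACF_RED",
    "KIND_CCF",
    "DegenerateROIError",
    "CorrelationSurface",
    "detrend",
    "spatial_correlation",
    "average_surfaces",
    "stack_correlation",
]

KIND_ACF_GREEN = "ACF_green"
KIND_ACF_RED = "ACF_red"
KIND_CCF = "CCF"
_ACF_KINDS = {KIND_ACF_GREEN, KIND_ACF_RED, "ACF"}


class DegenerateROIError(ValueError):
    """Raised for constant or (near-)zero-mean input images."""


@dataclasses.dataclass
class CorrelationSurface:
    """2D correlation values over signed spatial lags.

    ``values[i, j]`` is G at lag ``(psi_lags[i], xi_lags[j])`` where ``xi``
    runs along the fast (column) axis and ``psi`` along the slow (row) axis.
    """

    values: np.ndarray
    xi_lags: np.ndarray
    psi_lags: np.ndarray
    kind: str
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.xi_lags = np.asarray(self.xi_lags)
        self.psi_lags = np.asarray(self.psi_lags)
        if self.values.shape != (self.psi_lags.size, self.xi_lags.size):
            raise ValueError("values shape inconsistent with lag axes")

    @property
    def is_acf(self) -> bool:
        return self.kind in _ACF_KINDS

    def at(self, xi: int, psi: int) -> float:
        i = int(np.flatnonzero(self.psi_lags == psi)[0])
        j = int(np.flatnonzero(self.xi_lags == xi)[0])
        return float(self.values[i, j])

    def xi_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """The psi = 0 row for xi >= 0 — the profile the model is fitted to."""
        i0 = int(np.flatnonzero(self.psi_lags == 0)[0])
        j0 = int(np.flatnonzero(self.xi_lags == 0)[0])
        return self.xi_lags[j0:].copy(), self.values[i0, j0:].copy()

    def to_records(self):
        """Long-format (xi, psi, G) rows for CSV export."""
        psi, xi = np.meshgrid(self.psi_lags, self.xi_lags, indexing="ij")
        return np.column_stack([xi.ravel(), psi.ravel(), self.values.ravel()])


def detrend(stack: ImageStack, window: int = 3, mode: str = "subtract") -> ImageStack:
    """Remove slow temporal intensity changes (immobile fraction, structure).

    mode="subtract" (default): each frame has its centered ``window``-frame
    moving average subtracted and the global scalar mean restored, so the
    stack mean is preserved exactly while static spatial structure cancels.
    Boundary frames use a shrunken one-sided window.

    mode="replace": frames are replaced by their moving average (the literal
    smoothing reading), with the same mean restoration.
    """
    n = stack.n_frames
    if window < 2:
        raise ValueError("detrend window must be >= 2")
    if window > n:
        raise ValueError(f"detrend window {window} exceeds {n} frames")
    if mode not in ("subtract", "replace"):
        raise ValueError("mode must be 'subtract' or 'replace'")

    data = stack.data.astype(float)
    csum = np.concatenate([np.zeros((1,) + data.shape[1:]), np.cumsum(data, axis=0)])
    f = np.arange(n)
    lo = np.clip(f - (window - 1) // 2, 0, n)
    hi = np.clip(f + window // 2 + 1, 0, n)
    moving = (csum[hi] - csum[lo]) / (hi - lo)[:, None, None]

    global_mean = data.mean()
    out = moving if mode == "replace" else data - moving
    out = out - out.mean() + global_mean
    return stack.with_data(out, detrended=True)


def _overlap_counts(n_rows: int, n_cols: int) -> np.ndarray:
    rows = n_rows - np.abs(np.arange(-(n_rows - 1), n_rows))
    cols = n_cols - np.abs(np.arange(-(n_cols - 1), n_cols))
    return np.outer(rows, cols).astype(float)


def spatial_correlation(
    a: np.ndarray,
    b: np.ndarray | None = None,
    kind: str | None = None,
    on_degenerate: str = "raise",
) -> CorrelationSurface:
    """Correlate two images (ACF when ``b`` is None or ``b is a``).

    Degenerate inputs (constant image, or non-positive mean) raise
    :class:`DegenerateROIError` by default; with ``on_degenerate="zero"`` an
    all-zero surface is returned instead so callers can mark the ROI
    undefined without exception plumbing.
    """
    a = np.asarray(a, dtype=float)
    is_acf = b is None or b is a
    b_arr = a if is_acf else np.asarray(b, dtype=float)
    if a.shape != b_arr.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b_arr.shape}")
    if a.ndim != 2:
        raise ValueError("spatial_correlation expects 2D images")
    n_rows, n_cols = a.shape
    xi_lags = np.arange(-(n_cols - 1), n_cols)
    psi_lags = np.arange(-(n_rows - 1), n_rows)

    mean_a = a.mean()
    mean_b = b_arr.mean()
    da = a - mean_a
    db = b_arr - mean_b
    degenerate = (
        mean_a <= 0 or mean_b <= 0 or np.all(da == 0) or np.all(db == 0)
    )
    if degenerate:
        if on_degenerate == "zero":
            values = np.zeros((psi_lags.size, xi_lags.size))
            return CorrelationSurface(
                values, xi_lags, psi_lags, kind or ("ACF" if is_acf else KIND_CCF)
            )
        raise DegenerateROIError(
            "constant or non-positive-mean image; ROI has no fluctuations"
        )

    # full linear cross-correlation: index (psi + R - 1, xi + C - 1)
    num = signal.fftconvolve(db, da[::-1, ::-1], mode="full")
    values = num / _overlap_counts(n_rows, n_cols) / (mean_a * mean_b)
    if kind is None:
        kind = "ACF" if is_acf else KIND_CCF
    if kind in _ACF_KINDS:
        values = 0.5 * (values + values[::-1, ::-1])  # make even symmetry exact
    return CorrelationSurface(values, xi_lags, psi_lags, kind)


def average_surfaces(surfaces) -> CorrelationSurface:
    """Element-wise mean of surfaces sharing lag axes and kind."""
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("no surfaces to average")
    first = surfaces[0]
    total = np.zeros_like(first.values)
    n_frames = 0
    for s in surfaces:
        if s.kind != first.kind:
            raise ValueError(f"mixed surface kinds: {first.kind} vs {s.kind}")
        if not (
            np.array_equal(s.xi_lags, first.xi_lags)
            and np.array_equal(s.psi_lags, first.psi_lags)
        ):
            raise ValueError("mismatched lag axes")
        total += s.values
        n_frames += s.n_frames_averaged
    return CorrelationSurface(
        total / len(surfaces),
        first.xi_lags.copy(),
        first.psi_lags.copy(),
        first.kind,
        n_frames_averaged=n_frames,
    )


def stack_correlation(
    stack_a: ImageStack,
    stack_b: ImageStack | None = None,
    kind: str | None = None,
    roi: ROIWindow | None = None,
    frames: slice | None = None,
    on_degenerate: str = "raise",
) -> CorrelationSurface:
    """Per-frame spatial correlation of a stack (pair), averaged over frames."""
    data_a = stack_a.data
    data_b = data_a if stack_b is None else stack_b.data
    if frames is not None:
        data_a = data_a[frames]
        data_b = data_b[frames]
    if roi is not None:
        rs, cs = roi.slices
        data_a = data_a[:, rs, cs]
        data_b = data_b[:, rs, cs]
    if data_a.shape != data_b.shape:
        raise ValueError("stacks have different shapes")

    acc = None
    n = data_a.shape[0]
    for f in range(n):
        b_img = None if stack_b is None else data_b[f]
        surf = spatial_correlation(data_a[f], b_img, kind=kind, on_degenerate=on_degenerate)
        if acc is None:
            acc = surf
            acc.values = acc.values.copy()
        else:
            acc.values += surf.values
    acc.values /= n
    acc.n_frames_averaged = n
    return acc
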