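"""Spatiotemporal RCA mapping: half-overlapping ROI grids, per-ROI fits over
frame blocks, intensity-modulated map rendering, ROI time courses and
exponential decay kinetics.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .core_types import AcquisitionGeometry, ImageStack, ROIWindow, validate_stack_pair
from . import correlation as corr
from . import rics_fit

__all__ = [
    "ROIGrid",
    "RCAMap",
    "DecayFit",
    "tile_rois",
    "map_rca",
    "render_map",
    "roi_timecourse",
    "fit_rca_decay",
]


@dataclasses.dataclass(frozen=True)
class ROIGrid:
    """Half-overlapping ROI lattice.

    Anchors sit every ``roi_size / 2`` pixels; windows whose nominal extent
    crosses the image edge are truncated (default) or shifted back inside
    (``edge_mode="clamp"``).  With stride dividing the image size this gives
    exactly ``dim / stride`` anchors per axis (e.g. a 32 x 32 grid of
    64-pixel ROIs on a 1024-pixel image).
    """

    windows: tuple[ROIWindow, ...]
    n_grid_rows: int
    n_grid_cols: int
    roi_size: int
    anchor_stride: int
    edge_mode: str = "truncate"

    def window(self, grid_row: int, grid_col: int) -> ROIWindow:
        return self.windows[grid_row * self.n_grid_cols + grid_col]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_grid_rows, self.n_grid_cols)


def _axis_anchors(dim: int, stride: int) -> np.ndarray:
    return np.arange(0, dim - stride + 1, stride)


def tile_rois(
    image_shape: tuple[int, int], roi_size: int = 64, edge_mode: str = "truncate"
) -> ROIGrid:
    """Lay out half-overlapping ROIs over an image."""
    n_rows, n_cols = image_shape
    if roi_size > n_rows or roi_size > n_cols:
        raise ValueError(f"roi_size {roi_size} exceeds image shape {image_shape}")
    if roi_size % 2 or roi_size < 2 * ROIWindow.MIN_SIDE:
        raise ValueError(f"roi_size must be even and >= {2 * ROIWindow.MIN_SIDE}")
    if edge_mode not in ("truncate", "clamp"):
        raise ValueError("edge_mode must be 'truncate' or 'clamp'")
    stride = roi_size // 2
    row_anchors = _axis_anchors(n_rows, stride)
    col_anchors = _axis_anchors(n_cols, stride)
    windows = []
    for r in row_anchors:
        for c in col_anchors:
            if edge_mode == "clamp":
                rr = min(r, n_rows - roi_size)
                cc = min(c, n_cols - roi_size)
                windows.append(ROIWindow(rr, cc, roi_size, roi_size))
            else:
                windows.append(
                    ROIWindow(r, c, min(roi_size, n_rows - r), min(roi_size, n_cols - c))
                )
    return ROIGrid(
        windows=tuple(windows),
        n_grid_rows=row_anchors.size,
        n_grid_cols=col_anchors.size,
        roi_size=roi_size,
        anchor_stride=stride,
        edge_mode=edge_mode,
    )


@dataclasses.dataclass
class RCAMap:
    """Per-ROI, per-time-block RCA values plus mean intensities.

    Arrays are indexed (block, grid_row, grid_col); undefined entries (low
    intensity, degenerate ROI, failed fit) are NaN.  ``block_times`` is the
    mid-time of each frame block in seconds.
    """

    rca: np.ndarray
    mean_intensity_green: np.ndarray
    mean_intensity_red: np.ndarray
    diffusion_green: np.ndarray
    diffusion_red: np.ndarray
    block_times: np.ndarray
    grid: ROIGrid
    frames_per_block: int
    block_mode: str

    @property
    def n_blocks(self) -> int:
        return self.rca.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per (block, grid_row, grid_col)."""
        blocks, rows, cols = np.meshgrid(
            np.arange(self.n_blocks),
            np.arange(self.grid.n_grid_rows),
            np.arange(self.grid.n_grid_cols),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "block": blocks.ravel(),
                "time_s": np.repeat(self.block_times, self.grid.n_grid_rows * self.grid.n_grid_cols),
                "grid_row": rows.ravel(),
                "grid_col": cols.ravel(),
                "rca": self.rca.ravel(),
                "intensity_green": self.mean_intensity_green.ravel(),
                "intensity_red": self.mean_intensity_red.ravel(),
                "diffusion_green": self.diffusion_green.ravel(),
                "diffusion_red": self.diffusion_red.ravel(),
            }
        )


def _block_starts(n_frames: int, frames_per_block: int, block_mode: str) -> np.ndarray:
    if block_mode == "sliding":
        return np.arange(n_frames - frames_per_block + 1)
    if block_mode == "disjoint":
        return np.arange(0, n_frames - frames_per_block + 1, frames_per_block)
    raise ValueError("block_mode must be 'sliding' or 'disjoint'")


def map_rca(
    green: ImageStack,
    red: ImageStack,
    geometry: AcquisitionGeometry,
    grid: ROIGrid | None = None,
    frames_per_block: int = 10,
    block_mode: str = "sliding",
    intensity_threshold: float | None = None,
    roi_size: int = 64,
) -> RCAMap:
    """Run the per-ROI ccRICS fit over all ROIs and frame blocks.

    Expects detrended stacks.  For each ROI, per-frame ACF/ACF/CCF surfaces
    are computed once and block averages are formed from running sums; each
    averaged triple is fitted and RCA recorded.  ROIs whose block-mean
    intensity falls below ``intensity_threshold`` (default: 1% of the
    brighter stack's maximum) are marked undefined (NaN), as are failed fits.
    """
    validate_stack_pair(green, red)
    n_frames = green.n_frames
    if frames_per_block < 1 or frames_per_block > n_frames:
        raise ValueError(
            f"frames_per_block {frames_per_block} out of range for {n_frames} frames"
        )
    if grid is None:
        grid = tile_rois(green.frame_shape, roi_size=roi_size)
    if intensity_threshold is None:
        intensity_threshold = 0.01 * max(green.data.max(), red.data.max())

    starts = _block_starts(n_frames, frames_per_block, block_mode)
    n_blocks = starts.size
    shape = (n_blocks,) + grid.shape
    rca = np.full(shape, np.nan)
    int_g = np.full(shape, np.nan)
    int_r = np.full(shape, np.nan)
    d_g = np.full(shape, np.nan)
    d_r = np.full(shape, np.nan)

    for gr in range(grid.n_grid_rows):
        for gc in range(grid.n_grid_cols):
            win = grid.window(gr, gc)
            rs, cs = win.slices
            sub_g = green.data[:, rs, cs]
            sub_r = red.data[:, rs, cs]
            per_frame = _per_frame_surfaces(sub_g, sub_r)
            for bi, s in enumerate(starts):
                block = slice(s, s + frames_per_block)
                mg = float(sub_g[block].mean())
                mr = float(sub_r[block].mean())
                int_g[bi, gr, gc] = mg
                int_r[bi, gr, gc] = mr
                if min(mg, mr) < intensity_threshold or per_frame is None:
                    continue
                result = _fit_block(per_frame, block, frames_per_block, geometry)
                if result is not None and result.status == rics_fit.STATUS_OK:
                    rca[bi, gr, gc] = result.rca
                    d_g[bi, gr, gc] = result.D_g
                    d_r[bi, gr, gc] = result.D_r

    if np.all(np.isnan(rca)):
        warnings.warn("all ROIs undefined: empty RCA map", stacklevel=2)
    block_times = (starts + (frames_per_block - 1) / 2.0) * green.frame_interval
    return RCAMap(
        rca=rca,
        mean_intensity_green=int_g,
        mean_intensity_red=int_r,
        diffusion_green=d_g,
        diffusion_red=d_r,
        block_times=block_times,
        grid=grid,
        frames_per_block=frames_per_block,
        block_mode=block_mode,
    )


def _per_frame_surfaces(sub_g: np.ndarray, sub_r: np.ndarray):
    """Cumulative per-frame correlation sums for fast block averaging.

    Returns (csum_g, csum_r, csum_c, xi_lags, psi_lags) where each csum has
    shape (n_frames + 1, n_psi, n_xi), or None if any frame is degenerate.
    """
    n_frames = sub_g.shape[0]
    sums = None
    for f in range(n_frames):
        try:
            sg = corr.spatial_correlation(sub_g[f], kind=corr.KIND_ACF_GREEN)
            sr = corr.spatial_correlation(sub_r[f], kind=corr.KIND_ACF_RED)
            sc = corr.spatial_correlation(sub_g[f], sub_r[f], kind=corr.KIND_CCF)
        except corr.DegenerateROIError:
            return None
        if sums is None:
            shp = (n_frames + 1,) + sg.values.shape
            sums = (np.zeros(shp), np.zeros(shp), np.zeros(shp), sg.xi_lags, sg.psi_lags)
        for k, surf in enumerate((sg, sr, sc)):
            sums[k][f + 1] = sums[k][f] + surf.values
    return sums


def _fit_block(per_frame, block: slice, frames_per_block: int, geometry):
    csg, csr, csc, xi_lags, psi_lags = per_frame
    kinds = (corr.KIND_ACF_GREEN, corr.KIND_ACF_RED, corr.KIND_CCF)
    fits = []
    for cs, kind in zip((csg, csr, csc), kinds):
        avg = (cs[block.stop] - cs[block.start]) / frames_per_block
        surf = corr.CorrelationSurface(
            avg, xi_lags, psi_lags, kind, n_frames_averaged=frames_per_block
        )
        fits.append(rics_fit.fit_xi_profile(surf, geometry))
    return rics_fit.compute_rca(*fits)


def render_map(
    rca_map: RCAMap,
    image_shape: tuple[int, int],
    intensity_channel: str = "green",
    cmap: str = "jet",
    vmin: float = 0.0,
    vmax: float = 1.0,
) -> np.ndarray:
    """Render intensity-modulated RCA maps, one RGB frame per block.

    RCA is mapped to a red(high)-to-blue(low) color scale and interpolated
    bilinearly across the half-overlapping grid (values attach to window
    centres); pixel brightness is scaled by the normalized local mean
    fluorescence of the chosen channel.  Undefined ROIs render dark.
    """
    grid = rca_map.grid
    if intensity_channel == "green":
        intensity = rca_map.mean_intensity_green
    elif intensity_channel == "red":
        intensity = rca_map.mean_intensity_red
    else:
        raise ValueError("intensity_channel must be 'green' or 'red'")

    centers_r = np.array(
        [grid.window(i, 0).row_start + grid.window(i, 0).height / 2.0
         for i in range(grid.n_grid_rows)]
    )
    centers_c = np.array(
        [grid.window(0, j).col_start + grid.window(0, j).width / 2.0
         for j in range(grid.n_grid_cols)]
    )
    rows = np.arange(image_shape[0]) + 0.5
    cols = np.arange(image_shape[1]) + 0.5
    pr = np.clip(rows, centers_r[0], centers_r[-1])
    pc = np.clip(cols, centers_c[0], centers_c[-1])
    pts_r, pts_c = np.meshgrid(pr, pc, indexing="ij")
    pts = np.stack([pts_r.ravel(), pts_c.ravel()], axis=1)
    colormap = colormaps[cmap]

    frames = np.zeros((rca_map.n_blocks,) + tuple(image_shape) + (3,))
    span = max(vmax - vmin, 1e-12)
    for b in range(rca_map.n_blocks):
        rca = rca_map.rca[b]
        defined = np.isfinite(rca)
        inten = intensity[b]
        peak = np.nanmax(inten) if np.any(np.isfinite(inten)) else 0.0

        def interp(field, fill):
            filled = np.where(np.isfinite(field), field, fill)
            f = RegularGridInterpolator(
                (centers_r, centers_c), filled, method="linear"
            )
            return f(pts).reshape(image_shape)

        rca_img = interp(np.clip((rca - vmin) / span, 0.0, 1.0), 0.0)
        mask_img = interp(defined.astype(float), 0.0)
        inten_img = interp(inten / peak if peak > 0 else inten * 0.0, 0.0)
        rgb = colormap(rca_img)[..., :3]
        # hard-dark anything touching an undefined ROI; never interpolate over
        modulation = np.clip(inten_img, 0.0, 1.0) * (mask_img >= 1.0 - 1e-9)
        frames[b] = rgb * modulation[..., None]
    return frames


def roi_timecourse(
    rca_map: RCAMap, grid_row: int, grid_col: int, size: int = 3
) -> pd.DataFrame:
    """Mean and sample standard deviation of RCA over a ``size x size``
    block of grid cells (top-left corner at (grid_row, grid_col)), per block.
    """
    grid = rca_map.grid
    if (
        grid_row < 0
        or grid_col < 0
        or grid_row + size > grid.n_grid_rows
        or grid_col + size > grid.n_grid_cols
    ):
        raise ValueError(
            f"{size}x{size} selection at ({grid_row}, {grid_col}) lies outside "
            f"the {grid.shape} grid"
        )
    region = rca_map.rca[:, grid_row : grid_row + size, grid_col : grid_col + size]
    region = region.reshape(rca_map.n_blocks, -1)
    n_defined = np.isfinite(region).sum(axis=1)
    expected = size * size
    if np.any(n_defined < expected):
        warnings.warn(
            f"partial coverage: only {int(n_defined.min())}/{expected} grid "
            "cells defined in some blocks",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        mean = np.nanmean(region, axis=1)
        std = np.nanstd(region, axis=1, ddof=1)
    return pd.DataFrame(
        {
            "time_s": rca_map.block_times,
            "rca_mean": mean,
            "rca_std": std,
            "n_defined": n_defined,
        }
    )


@dataclasses.dataclass
class DecayFit:
    """Exponential decay RCA(t) = A * exp(-k t) + c, t in minutes."""

    amplitude: float
    rate: float  # 1/min
    offset: float
    residual: float
    rate_stderr: float
    status: str = rics_fit.STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == rics_fit.STATUS_OK

    def rate_ci(self, z: float = 1.96) -> tuple[float, float]:
        return (self.rate - z * self.rate_stderr, self.rate + z * self.rate_stderr)


def fit_rca_decay(
    times_min: np.ndarray, rca: np.ndarray, with_offset: bool = True
) -> DecayFit:
    """Least-squares exponential decay fit of an RCA time course.

    Initialized from a log-linear slope estimate; the rate is bounded to be
    non-negative.  A constant series therefore converges to (A ~ 0, k ~ 0).
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(rca, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values differ in length")
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size < 4:
        raise ValueError(f"need >= 4 time points to fit a decay, have {t.size}")

    c0 = float(np.min(y)) if with_offset else 0.0
    a0 = max(float(y[0] - c0), 1e-6)
    # log-linear slope of (y - c0) where positive; ~0 for flat data
    pos = (y - c0) > 1e-12
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos] - c0 + 1e-12), 1)[0]
        k0 = max(-float(slope), 0.0)
    else:
        k0 = 0.0

    if with_offset:
        def residuals(p):
            return p[0] * np.exp(-p[1] * t) + p[2] - y
        x0 = [a0, k0, c0]
        lower = [-np.inf, 0.0, -np.inf]
        upper = [np.inf, np.inf, np.inf]
    else:
        def residuals(p):
            return p[0] * np.exp(-p[1] * t) - y
        x0 = [a0, k0]
        lower = [-np.inf, 0.0]
        upper = [np.inf, np.inf]

    try:
        res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    except Exception:
        res = None
    if res is None or not res.success:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan, rics_fit.STATUS_FAILED)

    dof = max(t.size - len(x0), 1)
    resid_var = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = resid_var * np.linalg.inv(jtj)
        k_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        k_se = np.inf
    return DecayFit(
        amplitude=float(res.x[0]),
        rate=float(res.x[1]),
        offset=float(res.x[2]) if with_offset else 0.0,
        residual=float(2.0 * res.cost),
        rate_stderr=k_se,
    )
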