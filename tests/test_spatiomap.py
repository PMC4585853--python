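import numpy as np
import pytest
from matplotlib import colormaps

from ccrics.core_types import ImageStack
from ccrics.spatiomap import (
    DecayFit,
    RCAMap,
    fit_rca_decay,
    map_rca,
    render_map,
    roi_timecourse,
    tile_rois,
)


def make_map(rca, intensity=None, image_side=48, roi_size=32):
    """Hand-built RCAMap over a tile_rois grid for render/timecourse tests."""
    rca = np.asarray(rca, float)
    grid = tile_rois((image_side, image_side), roi_size=roi_size)
    assert rca.shape[1:] == grid.shape
    if intensity is None:
        intensity = np.ones_like(rca)
    n_blocks = rca.shape[0]
    return RCAMap(
        rca=rca,
        mean_intensity_green=np.asarray(intensity, float),
        mean_intensity_red=np.asarray(intensity, float),
        diffusion_green=np.full_like(rca, np.nan),
        diffusion_red=np.full_like(rca, np.nan),
        block_times=np.arange(n_blocks, dtype=float),
        grid=grid,
        frames_per_block=10,
        block_mode="sliding",
    )


class TestTileROIs:
    def test_1024_gives_32_by_32_grid(self):
        grid = tile_rois((1024, 1024), roi_size=64)
        assert grid.shape == (32, 32)
        assert grid.anchor_stride == 32
        assert len(grid.windows) == 1024

    def test_256_truncates_edge_windows(self):
        grid = tile_rois((256, 256), roi_size=64)
        assert grid.shape == (8, 8)
        corner = grid.window(7, 7)
        assert (corner.height, corner.width) == (32, 32)
        assert (corner.row_start, corner.col_start) == (224, 224)
        assert (grid.window(0, 0).height, grid.window(0, 0).width) == (64, 64)

    def test_clamp_mode_shifts_edge_windows(self):
        grid = tile_rois((256, 256), roi_size=64, edge_mode="clamp")
        corner = grid.window(7, 7)
        assert (corner.height, corner.width) == (64, 64)
        assert (corner.row_start, corner.col_start) == (192, 192)

    def test_roi_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            tile_rois((32, 32), roi_size=64)

    def test_bad_roi_size_rejected(self):
        with pytest.raises(ValueError):
            tile_rois((128, 128), roi_size=63)

    def test_bad_edge_mode_rejected(self):
        with pytest.raises(ValueError, match="edge_mode"):
            tile_rois((128, 128), roi_size=64, edge_mode="wrap")

    @pytest.mark.parametrize("shape,roi", [((128, 128), 32), ((96, 160), 32), ((256, 256), 64)])
    def test_every_pixel_covered_one_to_four_times(self, shape, roi):
        grid = tile_rois(shape, roi_size=roi)
        coverage = np.zeros(shape, dtype=int)
        for win in grid.windows:
            rs, cs = win.slices
            coverage[rs, cs] += 1
        assert coverage.min() >= 1
        assert coverage.max() <= 4


class TestMapRCA:
    def test_block_count_times_and_errors(self, rng):
        g = ImageStack(rng.poisson(20.0, size=(12, 32, 32)).astype(float), "green", 0.5)
        r = ImageStack(rng.poisson(20.0, size=(12, 32, 32)).astype(float), "red", 0.5)
        from ccrics.core_types import default_geometry

        geom = default_geometry(32, 32)
        result = map_rca(g, r, geom, frames_per_block=5, roi_size=32)
        assert result.n_blocks == 8  # sliding: 12 - 5 + 1
        assert np.all(np.diff(result.block_times) > 0)
        # block time = mid-time of the frame window
        assert result.block_times[0] == pytest.approx((5 - 1) / 2 * 0.5)

        disjoint = map_rca(g, r, geom, frames_per_block=5, roi_size=32, block_mode="disjoint")
        assert disjoint.n_blocks == 2

        with pytest.raises(ValueError, match="frames_per_block"):
            map_rca(g, r, geom, frames_per_block=13, roi_size=32)

    def test_low_intensity_rois_undefined(self, rng):
        data = rng.poisson(50.0, size=(10, 32, 32)).astype(float)
        data[:, :, 16:] = 0.0  # dark right half
        g = ImageStack(data, "green", 0.5)
        r = ImageStack(data.copy(), "red", 0.5)
        from ccrics.core_types import default_geometry

        geom = default_geometry(32, 32)
        result = map_rca(g, r, geom, frames_per_block=10, roi_size=32)
        # right-half anchor column mean intensity is recorded but RCA undefined
        assert np.isnan(result.rca[0, 0, 1])
        assert result.mean_intensity_green[0, 0, 1] < result.mean_intensity_green[0, 0, 0]

    def test_homogeneous_double_labeled_field(self, sim_double_d10, geom128):
        from ccrics.correlation import detrend

        green = detrend(sim_double_d10.green)
        red = detrend(sim_double_d10.red)
        result = map_rca(green, red, geom128, frames_per_block=30, roi_size=64)
        assert result.grid.shape == (4, 4)
        rca = result.rca[0]
        defined = np.isfinite(rca)
        assert defined.sum() >= 12
        assert np.nanmean(rca) >= 0.8
        # no spatial gradient: column index explains none of the variance
        cols = np.broadcast_to(np.arange(4), rca.shape)[defined]
        vals = rca[defined]
        slope, intercept = np.polyfit(cols, vals, 1)
        resid = vals - (slope * cols + intercept)
        se = np.sqrt(resid.var(ddof=2) / ((cols - cols.mean()) ** 2).sum())
        assert abs(slope) < 3 * se + 0.05

    def test_two_region_discrimination(self, sim_double_d10, sim_independent_d10, geom128):
        from ccrics.correlation import detrend

        # left half: double-labeled; right half: independent channels
        g = np.concatenate(
            [sim_double_d10.green.data[:, :, :64], sim_independent_d10.green.data[:, :, 64:]],
            axis=2,
        )
        r = np.concatenate(
            [sim_double_d10.red.data[:, :, :64], sim_independent_d10.red.data[:, :, 64:]],
            axis=2,
        )
        green = detrend(ImageStack(g, "green", 1.0))
        red = detrend(ImageStack(r, "red", 1.0))
        result = map_rca(green, red, geom128, frames_per_block=30, roi_size=64)
        left = result.rca[0, :, 0]  # windows cols 0..63: fully double-labeled
        right = result.rca[0, :, 3]  # windows cols 96..127: independent
        assert np.nanmean(left) - np.nanmean(right) >= 0.5

    def test_to_dataframe_long_format(self, rng):
        rmap = make_map(rng.uniform(0, 1, size=(2, 3, 3)))
        df = rmap.to_dataframe()
        assert len(df) == 2 * 9
        assert {"block", "grid_row", "grid_col", "rca", "intensity_green"} <= set(df.columns)
        row = df[(df.block == 1) & (df.grid_row == 2) & (df.grid_col == 0)].iloc[0]
        assert row.rca == rmap.rca[1, 2, 0]


class TestRenderMap:
    def test_constant_top_of_scale(self):
        rmap = make_map(np.ones((1, 3, 3)))
        frames = render_map(rmap, (48, 48))
        top = np.array(colormaps["jet"](1.0)[:3])
        assert frames.shape == (1, 48, 48, 3)
        np.testing.assert_allclose(frames[0], np.broadcast_to(top, (48, 48, 3)), atol=1e-12)

    def test_zero_intensity_renders_black(self):
        rmap = make_map(np.ones((1, 3, 3)), intensity=np.zeros((1, 3, 3)))
        frames = render_map(rmap, (48, 48))
        np.testing.assert_array_equal(frames, 0.0)

    def test_undefined_roi_rendered_dark(self):
        rca = np.ones((1, 3, 3))
        rca[0, 1, 1] = np.nan
        rmap = make_map(rca)
        frames = render_map(rmap, (48, 48))
        center = rmap.grid.window(1, 1)
        cy = center.row_start + center.height // 2
        cx = center.col_start + center.width // 2
        assert np.all(frames[0, cy, cx] == 0.0)
        assert frames[0].max() > 0  # defined corners still lit

    def test_interpolation_continuous_for_smooth_input(self):
        rmap = make_map(np.broadcast_to(np.linspace(0.2, 0.8, 3), (1, 3, 3)).copy())
        frames = render_map(rmap, (48, 48))
        lum = frames[0].sum(axis=2)
        # bilinear interpolation: per-pixel steps stay small everywhere (a
        # blocked rendering would jump by O(full scale) at anchor borders)
        assert np.abs(np.diff(lum, axis=1)).max() < 0.3
        assert np.abs(np.diff(lum, axis=0)).max() < 1e-12  # constant along rows

    def test_bad_channel_rejected(self):
        rmap = make_map(np.ones((1, 3, 3)))
        with pytest.raises(ValueError, match="intensity_channel"):
            render_map(rmap, (48, 48), intensity_channel="blue")


class TestROITimecourse:
    def test_constant_cells(self):
        rmap = make_map(np.full((2, 3, 3), 0.4))
        df = roi_timecourse(rmap, 0, 0)
        np.testing.assert_allclose(df.rca_mean, 0.4)
        np.testing.assert_allclose(df.rca_std, 0.0)
        np.testing.assert_array_equal(df.n_defined, 9)

    def test_known_mean_and_sample_std(self):
        cells = np.arange(0.1, 1.0, 0.1).reshape(1, 3, 3)
        df = roi_timecourse(make_map(cells), 0, 0)
        assert df.rca_mean[0] == pytest.approx(0.5)
        assert df.rca_std[0] == pytest.approx(np.sqrt(0.075))  # sample std, ddof=1

    def test_selection_outside_grid_rejected(self):
        rmap = make_map(np.ones((1, 3, 3)))
        with pytest.raises(ValueError, match="outside"):
            roi_timecourse(rmap, 2, 2)

    def test_partial_coverage_warns_with_count(self):
        rca = np.ones((1, 3, 3))
        rca[0, 0, 0] = np.nan
        with pytest.warns(UserWarning, match="8/9"):
            df = roi_timecourse(make_map(rca), 0, 0)
        assert df.n_defined[0] == 8


class TestFitRCADecay:
    def test_exact_model_recovered(self):
        t = np.linspace(0, 20, 15)
        y = 0.7 * np.exp(-0.2 * t)
        fit = fit_rca_decay(t, y)
        assert fit.ok
        assert fit.amplitude == pytest.approx(0.7, rel=1e-6)
        assert fit.rate == pytest.approx(0.2, rel=1e-6)
        assert abs(fit.offset) < 1e-6
        # invariant: A + c equals the t=0 value
        assert fit.amplitude + fit.offset == pytest.approx(y[0], rel=1e-6)

    def test_constant_series_flat_fit(self):
        t = np.linspace(0, 10, 12)
        fit = fit_rca_decay(t, np.full(12, 0.6))
        assert abs(fit.amplitude) < 1e-3
        assert fit.rate < 1e-6

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 15, 20)
        y = 0.7 * np.exp(-0.2 * t) + 0.05 + rng.normal(0, 0.03, t.size)
        fit = fit_rca_decay(t, y)
        assert fit.rate == pytest.approx(0.2, rel=0.1)

    def test_no_offset_variant(self):
        t = np.linspace(0, 20, 15)
        y = 0.5 * np.exp(-0.3 * t)
        fit = fit_rca_decay(t, y, with_offset=False)
        assert fit.offset == 0.0
        assert fit.rate == pytest.approx(0.3, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_rca_decay([0, 1, 2], [1.0, 0.5, 0.2])

    def test_nan_points_dropped(self):
        t = np.linspace(0, 10, 10)
        y = 0.8 * np.exp(-0.25 * t)
        y[3] = np.nan
        fit = fit_rca_decay(t, y)
        assert fit.rate == pytest.approx(0.25, rel=1e-5)

    def test_rate_ci(self):
        fit = DecayFit(0.7, 0.2, 0.0, 0.0, rate_stderr=0.01)
        lo, hi = fit.rate_ci()
        assert lo == pytest.approx(0.2 - 1.96 * 0.01)
        assert hi == pytest.approx(0.2 + 1.96 * 0.01)
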