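# ccrics

Cross-correlation raster image correlation spectroscopy (ccRICS) in Python:
a pipeline for quantifying the fraction of dual-labeled (intact) molecules
from two-channel raster-scanned fluorescence image stacks, plus a
Brownian-dynamics confocal-scan simulator that makes every stage testable
without microscope data.

The pipeline stages:

1. **Detrending** — a centered 3-frame moving average is subtracted from each
   frame (global mean restored), removing immobile structure while keeping
   diffusive fluctuations.
2. **Spatial correlation** — per-frame 2D auto- (per channel) and
   cross-correlation surfaces over pixel lags (ξ along the fast scan axis,
   ψ along the slow axis), computed as linear zero-padded FFT correlations
   with per-lag overlap normalization, averaged over 10-frame blocks.
3. **Model fitting** — nonlinear least squares of
   G(ξ, 0) = S(ξ, 0)·G_D(ξ, 0) (laser-scanning term × 3D free-diffusion
   term) along the ξ direction only, with the molecule number N and
   diffusion coefficient D free and the geometry (δr, τ_p, τ_l, w0, wz) and
   γ = 0.35 fixed.
4. **RCA** — the double-labeled molecule number N_gr = N_g·N_r/N_c from the
   apparent cross-correlation molecule number N_c, normalized as
   RCA = N_gr/N_g ∈ [0, ~1]: the fraction of green-labeled molecules that
   also carry the red label.
5. **Spatiotemporal mapping** — half-overlapping 64-px ROIs (a 32×32 grid on
   1024×1024 images), per-ROI fits over sliding frame blocks,
   intensity-modulated pseudocolor map rendering, nine-cell region time
   courses, and exponential decay fits RCA(t) = A·e^(−kt) + c.

The simulator scans 3D-diffusing point emitters (green-only, red-only, or
double-labeled species with known D, brightness, and counts) pixel-by-pixel
on the exact acquisition time lattice, with a 3D Gaussian PSF, periodic
boundaries, and Poisson shot noise — so recovered N, D, and RCA can be
checked against analytic ground truth.

## CLI

All stages are scriptable through the `ccrics` entry point; configuration is
a JSON document validated up front (unknown keys rejected):

```sh
ccrics simulate config.json simdata/           # TIFF pair + ground-truth JSON
ccrics correlate g.tif r.tif --config config.json --out surfaces.csv
ccrics fit g.tif r.tif --config config.json --out fit.json
ccrics run config.json g.tif r.tif results/    # end-to-end map bundle
ccrics decay series.csv --out decay.json       # exponential RCA(t) fit
```

A minimal config:

```json
{
  "geometry": {"pixel_size_um": 0.022, "pixel_dwell_us": 12.8,
               "line_time_us": 3276.8, "w0_um": 0.2, "wz_um": 1.0,
               "gamma": 0.35},
  "analysis": {"roi_size": 64, "frames_per_block": 10},
  "seed": 1
}
```

`run` writes `rca_map.csv` (long format: block, grid cell, RCA, mean
intensities, per-ROI D), `rca_map.json` metadata, per-block PNG maps, and a
`manifest.json` with the config hash and library versions; outputs are
byte-reproducible for a fixed seed.

## Layout

```
src/ccrics/
  core_types.py   acquisition geometry, image stacks, ROI windows, TIFF I/O
  simulator.py    Brownian-dynamics dual-channel raster-scan forward model
  correlation.py  detrending, FFT spatial correlation, frame averaging
  rics_fit.py     model terms, ξ-profile fitting, N_gr / RCA computation
  spatiomap.py    ROI tiling, RCA maps, rendering, time courses, decay fits
  cli_io.py       config schema, CLI subcommands, pipeline orchestration
```
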