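"""RICS model equations, xi-profile fitting, and cross-correlation amplitudes.

The fitted model factorizes into a laser-scanning term and a 3D
free-diffusion term,

    G(xi, psi) = S(xi, psi) * G_D(xi, psi)

    S   = exp(-[(dr*xi/w0)^2 + (dr*psi/w0)^2] / [1 + 4D(tau_p*xi + tau_l*psi)/w0^2])
    G_D = (gamma/N) * (1 + 4D(tau_p*xi + tau_l*psi)/w0^2)^-1
                    * (1 + 4D(tau_p*xi + tau_l*psi)/wz^2)^-1/2

with only N (mean molecule number in the observation volume) and D free;
geometry (dr, tau_p, tau_l, w0, wz) and gamma are calibration inputs.
Fitting is done along the xi direction only (psi = 0).

Cross-correlation amplitudes map to molecule numbers through
``G_c(0,0) = gamma * N_gr / (N_g * N_r)`` and the apparent
``N_c = gamma / G_c(0,0)``, giving ``N_gr = N_g * N_r / N_c`` and the
relative cross-correlation amplitude ``RCA = N_gr / N_g``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .core_types import AcquisitionGeometry, ImageStack, validate_stack_pair
from . import correlation as corr

__all__ = [
    "STATUS_OK",
    "STATUS_FAILED",
    "STATUS_AMPLITUDE_FLOOR",
    "RICSFitResult",
    "CrossCorrResult",
    "scan_term",
    "diffusion_term",
    "model_xi_profile",
    "fit_xi_profile",
    "compute_rca",
    "analyze_pair",
]

STATUS_OK = "ok"
STATUS_FAILED = "failed"
STATUS_AMPLITUDE_FLOOR = "amplitude_floor"

# restart multipliers applied to (N0, D0) for perturbed re-initialization
_RESTART_FACTORS = ((1.0, 1.0), (0.5, 2.0), (2.0, 0.5), (1.0, 10.0))


def _lag_time(xi, psi, geometry: AcquisitionGeometry):
    return geometry.pixel_dwell * np.asarray(xi) + geometry.line_time * np.asarray(psi)


def scan_term(xi, psi, geometry: AcquisitionGeometry, D: float):
    """Laser-scanning term S(xi, psi); S(0, 0) = 1 for any D.

    Defined for scan-forward lags (``tau_p*xi + tau_l*psi >= 0``).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    dr = geometry.pixel_size
    w0 = geometry.waist_lateral
    tau = _lag_time(xi, psi, geometry)
    denom = 1.0 + 4.0 * D * tau / w0**2
    arg = ((dr * np.asarray(xi) / w0) ** 2 + (dr * np.asarray(psi) / w0) ** 2) / denom
    return np.exp(-arg)


def diffusion_term(xi, psi, geometry: AcquisitionGeometry, N: float, D: float):
    """3D free-diffusion term G_D(xi, psi); G_D(0, 0) = gamma / N."""
    if not N > 0:
        raise ValueError(f"N must be > 0, got {N}")
    if D < 0:
        raise ValueError("D must be >= 0")
    w0 = geometry.waist_lateral
    wz = geometry.waist_axial
    tau = _lag_time(xi, psi, geometry)
    lat = 1.0 + 4.0 * D * tau / w0**2
    ax = 1.0 + 4.0 * D * tau / wz**2
    return (geometry.gamma / N) / (lat * np.sqrt(ax))


def model_xi_profile(xi, geometry: AcquisitionGeometry, N: float, D: float):
    """Full model along the fast axis: G(xi, 0) = S * G_D."""
    return scan_term(xi, 0, geometry, D) * diffusion_term(xi, 0, geometry, N, D)


def _xi_shape(xi, geometry, D):
    """Model profile with unit amplitude (N such that gamma/N = 1)."""
    return scan_term(xi, 0, geometry, D) * diffusion_term(xi, 0, geometry, geometry.gamma, D)


@dataclasses.dataclass
class RICSFitResult:
    """Outcome of a single xi-profile fit.

    ``amplitude`` is the fitted zero-lag value gamma/N (0 for
    amplitude-floored fits, where N is reported as inf).
    """

    N: float
    D: float
    residual: float
    n_points: int
    status: str = STATUS_OK
    amplitude: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclasses.dataclass
class CrossCorrResult:
    N_g: float
    N_r: float
    N_c: float
    N_gr: float
    rca: float
    D_g: float
    D_r: float
    status: str = STATUS_OK


def fit_xi_profile(
    surface: corr.CorrelationSurface,
    geometry: AcquisitionGeometry,
    xi_min: int | None = None,
    xi_max: int | None = None,
    amplitude_floor: float = 0.0,
) -> RICSFitResult:
    """Nonlinear least-squares fit of G(xi, 0) with free parameters N, D.

    Default fit ranges: xi in [1, width//4] for ACFs (the zero lag carries
    delta-correlated shot noise) and [0, width//4] for the CCF (shot noise
    is independent across detectors).  Initialization: N0 from the smallest
    fitted lag, D0 from a coarse log-grid search; a few bounded restarts
    from perturbed starts guard against local minima.

    A profile whose maximum over the fit range is <= ``amplitude_floor``
    yields an amplitude-floored result (N = inf, amplitude 0) which
    downstream maps to RCA = 0; optimizer failure yields status "failed".
    """
    xi, prof = surface.xi_profile()
    width = xi.size
    if xi_min is None:
        xi_min = 1 if surface.is_acf else 0
    if xi_max is None:
        xi_max = max(width // 4, xi_min + 7)
    xi_max = min(xi_max, width - 1)
    sel = (xi >= xi_min) & (xi <= xi_max)
    xi_fit = xi[sel].astype(float)
    y = prof[sel]
    n_points = y.size
    if n_points < 8:
        raise ValueError(f"need >= 8 xi lags to fit, have {n_points}")
    if not np.all(np.isfinite(y)):
        return RICSFitResult(np.nan, np.nan, np.nan, n_points, STATUS_FAILED)

    gamma = geometry.gamma
    if np.max(y) <= amplitude_floor:
        return RICSFitResult(
            np.inf, 0.0, float(np.sum(y**2)), n_points, STATUS_AMPLITUDE_FLOOR, 0.0
        )

    # coarse initialization: amplitude from smallest lag, D from log grid
    amp0 = y[0] if y[0] > 0 else float(np.max(y))
    best = (np.inf, amp0, 1.0)
    for D_try in np.logspace(-3, 4, 29):
        shape = _xi_shape(xi_fit, geometry, D_try)
        denom = float(shape @ shape)
        a = float(shape @ y) / denom if denom > 0 else 0.0
        if a <= 0:
            continue
        sse = float(np.sum((y - a * shape) ** 2))
        if sse < best[0]:
            best = (sse, a, D_try)
    _, amp0, D0 = best
    N0 = gamma / amp0

    def residuals(params):
        N, D = params
        return model_xi_profile(xi_fit, geometry, N, D) - y

    lower = [1e-10, 0.0]
    upper = [1e12, 1e8]
    best_fit = None
    for fn, fd in _RESTART_FACTORS:
        x0 = [
            float(np.clip(N0 * fn, lower[0], upper[0])),
            float(np.clip(D0 * fd, lower[1], upper[1])),
        ]
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if not res.success:
            continue
        if best_fit is None or res.cost < best_fit.cost:
            best_fit = res
    if best_fit is None:
        return RICSFitResult(np.nan, np.nan, np.nan, n_points, STATUS_FAILED)
    N_fit, D_fit = best_fit.x
    return RICSFitResult(
        N=float(N_fit),
        D=float(D_fit),
        residual=float(2.0 * best_fit.cost),
        n_points=n_points,
        status=STATUS_OK,
        amplitude=float(gamma / N_fit),
    )


def compute_rca(
    fit_g: RICSFitResult, fit_r: RICSFitResult, fit_c: RICSFitResult
) -> CrossCorrResult:
    """Combine the three channel fits into molecule numbers and RCA.

    N_gr = N_g * N_r / N_c and RCA = N_gr / N_g (= N_r / N_c).  A
    non-positive cross amplitude means no detectable double-labeled species:
    N_gr = 0 and RCA = 0.  RCA is clamped to >= 0.
    """
    for name, fit in (("green", fit_g), ("red", fit_r)):
        if fit is None:
            raise ValueError(f"missing {name}-channel fit")
        if fit.status != STATUS_OK:
            return CrossCorrResult(
                N_g=fit_g.N, N_r=fit_r.N, N_c=np.nan, N_gr=np.nan, rca=np.nan,
                D_g=fit_g.D, D_r=fit_r.D, status=STATUS_FAILED,
            )
    if fit_c is None:
        raise ValueError("missing cross-correlation fit")
    if fit_c.status == STATUS_FAILED:
        return CrossCorrResult(
            N_g=fit_g.N, N_r=fit_r.N, N_c=np.nan, N_gr=np.nan, rca=np.nan,
            D_g=fit_g.D, D_r=fit_r.D, status=STATUS_FAILED,
        )
    if fit_c.status == STATUS_AMPLITUDE_FLOOR or fit_c.amplitude <= 0:
        return CrossCorrResult(
            N_g=fit_g.N, N_r=fit_r.N, N_c=np.inf, N_gr=0.0, rca=0.0,
            D_g=fit_g.D, D_r=fit_r.D, status=STATUS_OK,
        )
    N_gr = fit_g.N * fit_r.N / fit_c.N
    rca = max(N_gr / fit_g.N, 0.0)
    return CrossCorrResult(
        N_g=fit_g.N, N_r=fit_r.N, N_c=fit_c.N, N_gr=N_gr, rca=rca,
        D_g=fit_g.D, D_r=fit_r.D, status=STATUS_OK,
    )


def analyze_pair(
    green: ImageStack,
    red: ImageStack,
    geometry: AcquisitionGeometry,
    roi=None,
    frames: slice | None = None,
    detrend_window: int | None = 3,
    xi_max: int | None = None,
) -> CrossCorrResult:
    """Whole-field (or single-ROI) ccRICS analysis of a stack pair.

    Runs optional detrending, per-frame ACF/ACF/CCF computation averaged
    over frames, xi-profile fits of all three surfaces, and the RCA
    computation.  ``detrend_window=None`` skips detrending (useful for
    amplitude-calibration work on stationary simulations).
    """
    validate_stack_pair(green, red)
    if detrend_window is not None:
        green = corr.detrend(green, window=detrend_window)
        red = corr.detrend(red, window=detrend_window)
    surf_g = corr.stack_correlation(green, kind=corr.KIND_ACF_GREEN, roi=roi, frames=frames)
    surf_r = corr.stack_correlation(red, kind=corr.KIND_ACF_RED, roi=roi, frames=frames)
    surf_c = corr.stack_correlation(green, red, kind=corr.KIND_CCF, roi=roi, frames=frames)
    fit_g = fit_xi_profile(surf_g, geometry, xi_max=xi_max)
    fit_r = fit_xi_profile(surf_r, geometry, xi_max=xi_max)
    fit_c = fit_xi_profile(surf_c, geometry, xi_max=xi_max)
    return compute_rca(fit_g, fit_r, fit_c)
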