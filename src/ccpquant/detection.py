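"""Diffraction-limited spot detection by 2D Gaussian fitting.

Spots are assumed well approximated by an isotropic 2D Gaussian on a locally
constant background.  Candidate pixels come from a difference-of-Gaussians
band-pass matched to the PSF width; each candidate is then fit by least
squares over a small window,

    I(x, y) = A exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2)) + c,

with sigma fixed to the configured PSF width by default.  Significance is a
one-sided test of the fitted amplitude against the residual background noise
at that location: the statistic (A - k * residual_noise_sd) / SE(A) is
referred to a t distribution with (window pixels - free parameters) degrees
of freedom.  The offset k (default 2) demands that a detection clearly
exceed the local noise floor, which keeps the false-positive rate at or
below alpha even though candidates are selected at local maxima.

Detection runs on a "master" channel; slave channels are quantified
dependently — for every master detection a Gaussian is fit in the slave
channel with the position constrained near the master position, so a slave
measurement (significant or not) exists for every master spot.

Coordinates are 0-based, pixel-center: x is the column index, y the row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from skimage.feature import peak_local_max

__all__ = [
    "DetectionConfig",
    "SpotDetection",
    "find_candidates",
    "fit_spot",
    "detect_frame",
    "measure_slave",
    "detections_to_frame",
]


@dataclass
class DetectionConfig:
    """Tunables of the detection step.

    psf_sigma: Gaussian PSF width in pixels (fixed during fits by default).
    alpha: significance level of the amplitude test.
    amplitude_test_k: null offset, amplitude must exceed k * residual noise SD.
    window_radius: half-width of the square fit window (>= 2 * psf_sigma).
    position_tolerance: how far the fit may move the center from the seed.
    slave_search_radius: position constraint for dependent slave fits.
    fit_sigma: if True, refit with sigma free after the fixed-sigma fit.
    """

    psf_sigma: float = 1.1
    alpha: float = 0.05
    amplitude_test_k: float = 2.0
    window_radius: int = 5
    position_tolerance: float = 2.0
    slave_search_radius: float = 2.0
    fit_sigma: bool = False
    candidate_threshold_sigma: float = 3.0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_radius < 2 * self.psf_sigma:
            raise ValueError("window_radius must be >= 2 * psf_sigma")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


@dataclass
class SpotDetection:
    """One fitted spot (or one dependent slave measurement)."""

    frame: int
    channel: str
    x: float
    y: float
    sigma: float
    amplitude: float
    background: float
    residual_noise_sd: float
    p_value: float
    significant: bool
    valid: bool = True
    seed_x: int = 0
    seed_y: int = 0


def detections_to_frame(detections: list[SpotDetection]) -> pd.DataFrame:
    """Tabulate detections (coordinates 0-based, pixel-center, x = column)."""
    return pd.DataFrame(
        [
            {
                "frame": d.frame, "channel": d.channel, "x": d.x, "y": d.y,
                "sigma": d.sigma, "amplitude": d.amplitude,
                "background": d.background, "noise_sd": d.residual_noise_sd,
                "p_value": d.p_value, "significant": d.significant,
                "valid": d.valid,
            }
            for d in detections
        ],
        columns=["frame", "channel", "x", "y", "sigma", "amplitude",
                 "background", "noise_sd", "p_value", "significant", "valid"],
    )


def find_candidates(frame: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Integer pixel seeds: DoG band-pass local maxima above a low threshold.

    Returns an (n, 2) array of (x, y) pixel positions.  The threshold is
    deliberately permissive (a small multiple of the robust DoG noise SD);
    the amplitude test in :func:`fit_spot` is the real gatekeeper.  Seeds too
    close to the border for a full fit window are excluded.
    """
    config.validate()
    frame = np.asarray(frame, float)
    if frame.size == 0:
        raise ValueError("empty frame")
    s = config.psf_sigma
    dog = ndimage.gaussian_filter(frame, s) - ndimage.gaussian_filter(frame, 1.6 * s)
    if np.ptp(dog) == 0:
        return np.empty((0, 2), dtype=int)
    mad = np.median(np.abs(dog - np.median(dog)))
    thresh = config.candidate_threshold_sigma * 1.4826 * mad
    # noiseless frames have MAD 0; floor the threshold so flat background
    # plateaus are never reported as candidates
    thresh = max(thresh, 1e-6 * float(dog.max()))
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(round(2 * s))),
        threshold_abs=thresh,
        exclude_border=config.window_radius,
    )
    # peak_local_max returns (row, col); report (x, y)
    return peaks[:, ::-1].copy()


def _gauss2d(params, xs, ys, sigma):
    A, x0, y0, c = params
    return A * np.exp(-((xs - x0) ** 2 + (ys - y0) ** 2) / (2.0 * sigma**2)) + c


def fit_spot(frame: np.ndarray, seed_position, config: DetectionConfig,
             frame_index: int = 0, channel: str = "master",
             position_tolerance: float | None = None) -> SpotDetection:
    """Least-squares Gaussian fit at one candidate position.

    ``seed_position`` is (x, y) with a full fit window inside the frame.
    The center may move at most ``position_tolerance`` pixels (default from
    config) from the seed.  Non-convergence yields ``valid=False`` (never a
    silent drop).
    """
    config.validate()
    frame = np.asarray(frame, float)
    sx, sy = int(round(seed_position[0])), int(round(seed_position[1]))
    r = config.window_radius
    h, w = frame.shape
    if not (r <= sx < w - r and r <= sy < h - r):
        raise ValueError(f"seed ({sx},{sy}) lacks a full {2*r+1}px window")
    tol = config.position_tolerance if position_tolerance is None else position_tolerance

    patch = frame[sy - r: sy + r + 1, sx - r: sx + r + 1]
    ys, xs = np.mgrid[sy - r: sy + r + 1, sx - r: sx + r + 1]
    xs = xs.ravel().astype(float)
    ys = ys.ravel().astype(float)
    z = patch.ravel()
    sigma = config.psf_sigma

    c0 = float(np.median(z))
    A0 = max(float(frame[sy, sx] - c0), 1e-6)
    p0 = np.array([A0, float(sx), float(sy), c0])
    lb = np.array([-np.inf, sx - tol, sy - tol, -np.inf])
    ub = np.array([np.inf, sx + tol, sy + tol, np.inf])

    def resid(p):
        return _gauss2d(p, xs, ys, sigma) - z

    def jac(p):
        A, x0, y0, c = p
        dx = xs - x0
        dy = ys - y0
        e = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
        J = np.empty((z.size, 4))
        J[:, 0] = e
        J[:, 1] = A * e * dx / sigma**2
        J[:, 2] = A * e * dy / sigma**2
        J[:, 3] = 1.0
        return J

    try:
        # unconstrained LM first (fast); refit with bounds only if the center
        # wandered outside the allowed radius
        sol = optimize.least_squares(resid, p0, jac=jac, method="lm",
                                     max_nfev=100)
        if not (lb[1] <= sol.x[1] <= ub[1] and lb[2] <= sol.x[2] <= ub[2]):
            sol = optimize.least_squares(resid, p0, jac=jac, bounds=(lb, ub),
                                         max_nfev=100)
    except Exception:
        return SpotDetection(frame_index, channel, float(sx), float(sy), sigma,
                             0.0, c0, 0.0, 1.0, False, valid=False,
                             seed_x=sx, seed_y=sy)
    A, x0, y0, c = sol.x

    if config.fit_sigma:
        def resid_s(p):
            return _gauss2d(p[:4], xs, ys, p[4]) - z
        try:
            sol2 = optimize.least_squares(
                resid_s, np.append(sol.x, sigma),
                bounds=(np.append(lb, 0.3 * sigma), np.append(ub, 3.0 * sigma)),
                max_nfev=200)
            if sol2.success:
                A, x0, y0, c, sigma = sol2.x
                sol = sol2
        except Exception:
            pass

    n_params = 5 if config.fit_sigma else 4
    dof = max(z.size - n_params, 1)
    res = sol.fun
    rss = float(res @ res)
    noise_sd = float(np.sqrt(rss / dof))
    # SE(A) from the Jacobian of the converged fit
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
        se_A = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_A = np.nan
    if not np.isfinite(se_A) or se_A == 0:
        # zero residual noise: significance degenerates to the raw comparison
        above = A > config.amplitude_test_k * noise_sd
        p_value, significant = (0.0, True) if above else (1.0, False)
    else:
        t_stat = (A - config.amplitude_test_k * noise_sd) / se_A
        p_value = float(stats.t.sf(t_stat, dof))
        significant = p_value < config.alpha
    return SpotDetection(frame_index, channel, float(x0), float(y0),
                         float(sigma), float(A), float(c), noise_sd,
                         p_value, bool(significant), valid=bool(sol.success),
                         seed_x=sx, seed_y=sy)


def detect_frame(frame: np.ndarray, config: DetectionConfig,
                 frame_index: int = 0, channel: str = "master",
                 keep_insignificant: bool = False) -> list[SpotDetection]:
    """Find, fit, deduplicate and filter all spots in one frame.

    Deterministic.  Duplicate fits converging within 1 px of each other are
    merged keeping the higher amplitude.  By default only significant
    detections are returned; ``keep_insignificant`` retains the rest for
    diagnostics.
    """
    seeds = find_candidates(frame, config)
    dets = [fit_spot(frame, s, config, frame_index, channel) for s in seeds]
    dets.sort(key=lambda d: -d.amplitude)
    kept: list[SpotDetection] = []
    for d in dets:
        if any((d.x - k.x) ** 2 + (d.y - k.y) ** 2 < 1.0 for k in kept):
            continue
        kept.append(d)
    if not keep_insignificant:
        kept = [d for d in kept if d.significant and d.valid]
    return kept


def measure_slave(master_detections: list[SpotDetection], slave_frame: np.ndarray,
                  config: DetectionConfig, channel: str = "slave",
                  master_frame_shape: tuple[int, int] | None = None
                  ) -> list[SpotDetection]:
    """Dependent slave-channel quantification, paired 1:1 with the masters.

    For every master detection a Gaussian is fit in the slave channel with
    the center constrained within ``slave_search_radius`` of the master
    position; the amplitude is significance-tested exactly as in
    :func:`fit_spot`.  The k-th output corresponds to the k-th master.
    """
    slave_frame = np.asarray(slave_frame, float)
    if master_frame_shape is not None and slave_frame.shape != master_frame_shape:
        raise ValueError("slave frame geometry differs from master frame")
    out: list[SpotDetection] = []
    r = config.window_radius
    h, w = slave_frame.shape
    for m in master_detections:
        sx, sy = int(round(m.x)), int(round(m.y))
        sx = min(max(sx, r), w - r - 1)
        sy = min(max(sy, r), h - r - 1)
        det = fit_spot(slave_frame, (sx, sy), config, m.frame, channel,
                       position_tolerance=config.slave_search_radius)
        out.append(det)
    return out
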