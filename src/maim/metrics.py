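"""Quantitative validation: depth-accuracy Monte Carlo, sphere-cap
fitting, and lateral-resolution checks.

These routines close the loop on the synthetic phantoms: render a scene
whose geometry is known exactly, run the reconstruction, and measure how
far the recovered depths or profiles are from the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .depth import DepthMap, SolverParams, solve_batch
from .optics import AngleGrid, AxialGrid, OpticalConfig, build_system_matrix
from .phantoms import (
    FWHM_TO_SIGMA,
    NoiseModel,
    Scene,
    default_psf_fwhm_nm,
    make_point_scene,
    render_matirf_stack,
    _splat_gaussians,
)

__all__ = [
    "RMSEReport",
    "SphereFit",
    "ground_truth_depth_map",
    "depth_rmse",
    "point_depth_realizations",
    "rmse_vs_snr_curve",
    "fit_sphere_cap",
    "line_pair_resolved",
    "fwhm",
]


@dataclass(frozen=True)
class RMSEReport:
    """Monte-Carlo depth-accuracy grid over (true depth, SNR)."""

    table: pd.DataFrame  # columns: depth_nm, snr, rmse_nm, se_nm, n_reps
    seed: int
    settings: dict[str, Any] = field(default_factory=dict)

    def rmse(self, depth_nm: float, snr: float) -> float:
        row = self.table[
            (self.table.depth_nm == depth_nm) & (self.table.snr == snr)
        ]
        if row.empty:
            raise KeyError(f"no cell for depth={depth_nm}, snr={snr}")
        return float(row.rmse_nm.iloc[0])


@dataclass(frozen=True)
class SphereFit:
    """Least-squares spherical-cap fit of a depth map."""

    radius_nm: float
    center_nm: tuple[float, float]
    residual_rms_nm: float
    n_pixels: int

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_nm / 1000.0


def ground_truth_depth_map(
    scene: Scene,
    config: OpticalConfig,
    shape: tuple[int, int],
    psf_fwhm_nm: float | None = None,
    mode: str = "profile",
) -> np.ndarray:
    """Per-pixel ground-truth depth of a scene.

    ``mode='profile'`` (default) weights each emitter's depth by its PSF
    contribution to the pixel — the depth an ideal axial reconstruction
    of that pixel would report.  ``mode='nearest'`` takes the depth of
    the laterally nearest emitter.  Pixels with no signal are NaN.
    """
    if psf_fwhm_nm is None:
        psf_fwhm_nm = default_psf_fwhm_nm(config)
    if mode == "profile":
        sigma = psf_fwhm_nm * FWHM_TO_SIGMA
        den = _splat_gaussians(
            scene, scene.brightness, shape, config.pixel_nm, sigma
        )
        num = _splat_gaussians(
            scene, scene.brightness * scene.z, shape, config.pixel_nm, sigma
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            truth = num / den
        return np.where(den > 1e-12 * den.max(), truth, np.nan)
    if mode == "nearest":
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([scene.x, scene.y]))
        yy, xx = np.meshgrid(
            (np.arange(shape[0]) + 0.5) * config.pixel_nm,
            (np.arange(shape[1]) + 0.5) * config.pixel_nm,
            indexing="ij",
        )
        _, i = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
        return scene.z[i].reshape(shape)
    raise ValueError(f"unknown ground-truth mode {mode!r}")


def depth_rmse(
    depth_map: DepthMap,
    scene: Scene,
    config: OpticalConfig,
    psf_fwhm_nm: float | None = None,
    mode: str = "profile",
) -> float:
    """RMSE of the recovered per-pixel mean depth against the scene's
    ground truth, over in-mask pixels with a defined depth."""
    truth = ground_truth_depth_map(
        scene, config, depth_map.h.shape, psf_fwhm_nm, mode
    )
    valid = depth_map.mask & np.isfinite(depth_map.h) & np.isfinite(truth)
    if not np.any(valid):
        raise ValueError("no valid pixels to compare")
    err = depth_map.h[valid] - truth[valid]
    return float(np.sqrt(np.mean(err**2)))


def point_depth_realizations(
    z_nm: float,
    snr: float,
    angle_grid: AngleGrid,
    config: OpticalConfig,
    axial_grid: AxialGrid | None = None,
    n_reps: int = 100,
    seed: int = 0,
    params: SolverParams | None = None,
    extent_nm: float = 1664.0,
    pool_px: int = 1,
) -> np.ndarray:
    """Recovered mean depths of a single bright emitter over noise
    realizations.

    Each realization renders the multi-angle stack of a centered point
    emitter at ``z_nm`` with fresh noise, pools the pixel intensities in
    a (2*pool_px+1)^2 neighborhood of the emitter (the emitter's PSF
    spot), and inverts the pooled K-vector.  All realizations are solved
    as one ADMM batch.
    """
    if params is None:
        params = SolverParams()
    if axial_grid is None:
        axial_grid = AxialGrid.from_range()
    scene = make_point_scene(z_nm=z_nm, extent_nm=extent_nm)
    sysmat = build_system_matrix(angle_grid, axial_grid, config)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    bvecs = np.empty((angle_grid.k, n_reps))
    for r in range(n_reps):
        noise = None if np.isinf(snr) else NoiseModel(snr=snr, seed=int(seeds[r]))
        stack = render_matirf_stack(scene, angle_grid, config, noise=noise)
        frames = stack.frames_by_angle().mean(axis=1)
        cy, cx = (np.array(frames.shape[1:]) // 2) - 0 # emitter at center
        sl = np.s_[
            :,
            cy - pool_px : cy + pool_px + 1,
            cx - pool_px : cx + pool_px + 1,
        ]
        pooled = np.clip(frames[sl], 0.0, None).sum(axis=(1, 2))
        bvecs[:, r] = pooled
    f, _, _, _ = solve_batch(bvecs, sysmat, params)
    totals = f.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (axial_grid.z_nm @ f) / totals
    return np.where(totals > 0, h, np.nan)


def rmse_vs_snr_curve(
    snr_list,
    depth_list,
    angle_grid: AngleGrid,
    config: OpticalConfig,
    n_reps: int = 30,
    seed: int = 0,
    axial_grid: AxialGrid | None = None,
    params: SolverParams | None = None,
) -> RMSEReport:
    """Monte-Carlo depth RMSE on a (depth x SNR) grid for a single bright
    emitter, with per-cell standard errors."""
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per cell")
    rows = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(len(list(depth_list)) * len(list(snr_list)))
    i = 0
    for z in depth_list:
        for snr in snr_list:
            h = point_depth_realizations(
                z,
                snr,
                angle_grid,
                config,
                axial_grid=axial_grid,
                n_reps=n_reps,
                seed=int(cell_seeds[i]),
                params=params,
            )
            i += 1
            sq = (h - z) ** 2
            rmse = float(np.sqrt(np.nanmean(sq)))
            se = float(
                np.nanstd(sq, ddof=1) / np.sqrt(n_reps) / (2 * max(rmse, 1e-9))
            )
            rows.append(
                {
                    "depth_nm": float(z),
                    "snr": float(snr),
                    "rmse_nm": rmse,
                    "se_nm": se,
                    "n_reps": n_reps,
                }
            )
    table = pd.DataFrame(rows)
    return RMSEReport(
        table=table,
        seed=seed,
        settings={
            "theta_deg": list(angle_grid.theta_deg),
            "n_reps": n_reps,
        },
    )


def fit_sphere_cap(
    depth_map: DepthMap,
    pixel_nm: float,
    h_max_nm: float = 400.0,
    r_init_nm: float | None = None,
    loss: str = "soft_l1",
    f_scale_nm: float = 30.0,
) -> SphereFit:
    """Fit h(x, y) = R - sqrt(R^2 - r^2) to a coverslip-attached sphere's
    depth map and return the recovered radius and contact point.

    The fit runs over in-mask pixels with recovered depth up to
    ``h_max_nm``; the default of 400 nm is about 1.3x the deepest
    penetration depth of a 61.5 deg starting angle, beyond which the
    excitation is too weak for reliable per-pixel depths and the mask
    rim is dominated by PSF halo.  A robust loss (soft-l1, scale ~30 nm)
    is used because per-pixel depth errors are heavy-tailed.  Residuals
    are unweighted: intensity weighting would let the bright flat
    contact region, which carries almost no curvature information,
    dominate the radius.  The intensity map only seeds the contact-point
    estimate.
    """
    valid = depth_map.mask & np.isfinite(depth_map.h) & (depth_map.h <= h_max_nm)
    rows, cols = np.nonzero(valid)
    if rows.size < 20:
        raise ValueError(f"only {rows.size} valid pixels; need >= 20")
    x = (cols + 0.5) * pixel_nm
    y = (rows + 0.5) * pixel_nm
    h = depth_map.h[rows, cols]
    w = np.clip(depth_map.intensity[rows, cols], 0, None)
    w = w / max(w.max(), 1e-300)
    x0 = float(np.sum(x * w) / w.sum())
    y0 = float(np.sum(y * w) / w.sum())
    if r_init_nm is None:
        r2 = (x - x0) ** 2 + (y - y0) ** 2
        deep = h > max(20.0, 0.1 * h.max())
        if np.any(deep):
            r_init_nm = float(np.median((r2[deep] + h[deep] ** 2) / (2 * h[deep])))
        else:
            r_init_nm = 2000.0

    def model(p):
        rr, cx, cy = p
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        inside = np.clip(rr**2 - r2, 0.0, None)
        return rr - np.sqrt(inside)

    def resid(p):
        return model(p) - h

    fit = least_squares(
        resid,
        x0=[r_init_nm, x0, y0],
        bounds=([1.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        method="trf",
        loss=loss,
        f_scale=f_scale_nm,
    )
    if not fit.success:
        raise RuntimeError(f"sphere-cap fit did not converge: {fit.message}")
    rr, cx, cy = fit.x
    res = model(fit.x) - h
    return SphereFit(
        radius_nm=float(rr),
        center_nm=(float(cx), float(cy)),
        residual_rms_nm=float(np.sqrt(np.mean(res**2))),
        n_pixels=int(rows.size),
    )


def sphere_recovery_experiment(
    n_spheres: int = 4,
    seed: int = 0,
    diameter_um: float = 4.86,
    snr: float = 30.0,
    n_azimuth: int = 4,
    field_px: int = 80,
    surface_density_per_um2: float = 400.0,
    z_cap_max_nm: float = 500.0,
    config: OpticalConfig | None = None,
    angle_grid: AngleGrid | None = None,
) -> tuple[float, list[SphereFit]]:
    """End-to-end sphere ground-truth recovery.

    For each sphere: simulate a surface-labeled microsphere resting on
    the coverslip, render its ring-TIRF multi-angle stack and SIM raw
    set at the given SNR, reconstruct the lateral SR image, mask
    (fixed 5% threshold — keeps the dim deep rim that Otsu discards),
    subtract background, invert to a depth map, and fit the spherical
    cap.  Returns the mean fitted diameter (um) and individual fits.
    """
    from .segment import make_mask as _make_mask
    from .segment import subtract_background as _subtract_background
    from .simrecon import nominal_pattern_estimate as _nominal
    from .simrecon import reconstruct as _reconstruct
    from .depth import SolverParams as _SolverParams
    from .depth import solve_volume as _solve_volume
    from .phantoms import make_sphere_scene, render_sim_rawset

    if config is None:
        config = OpticalConfig()
    if angle_grid is None:
        angle_grid = AngleGrid.from_start_step(61.5, 0.5, 20, n_azimuth)
    axial = AxialGrid.from_range()
    sysmat = build_system_matrix(
        AngleGrid(angle_grid.theta_deg), axial, config
    )
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_spheres)
    fits: list[SphereFit] = []
    for i in range(n_spheres):
        scene = make_sphere_scene(
            diameter_um=diameter_um,
            extent_nm=field_px * config.pixel_nm,
            surface_density_per_um2=surface_density_per_um2,
            z_cap_max_nm=z_cap_max_nm,
            seed=int(seeds[3 * i]),
        )
        stack = render_matirf_stack(
            scene,
            angle_grid,
            config,
            noise=NoiseModel(snr=snr, seed=int(seeds[3 * i + 1])),
        )
        raw = render_sim_rawset(
            scene, config, noise=NoiseModel(snr=snr, seed=int(seeds[3 * i + 2]))
        )
        sr = _reconstruct(raw, pattern=_nominal(raw))
        mask = _make_mask(sr, method="fixed", threshold=0.05)
        segmented = _subtract_background(stack, mask)
        dm = _solve_volume(segmented, sysmat, _SolverParams())
        fits.append(fit_sphere_cap(dm, config.pixel_nm))
    mean_diam = float(np.mean([f.diameter_um for f in fits]))
    return mean_diam, fits


def _subpixel_peak(profile: np.ndarray, i: int) -> float:
    """Quadratic-interpolated peak position around index i."""
    if 0 < i < profile.size - 1:
        y0, y1, y2 = profile[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return i + 0.5 * (y0 - y2) / denom
    return float(i)


def line_pair_resolved(
    image: np.ndarray,
    pixel_nm: float,
    axis: int = 0,
    min_dip_fraction: float = 0.2,
) -> tuple[bool, float, float]:
    """Two-line Rayleigh-style resolution test on an image of parallel
    lines.

    Averages the image along the line direction (``axis``), finds the two
    strongest local maxima, and declares the pair resolved when the
    valley between them is at most (1 - min_dip_fraction) times the lower
    peak.  Returns (resolved, peak separation in nm, dip fraction).
    """
    profile = np.clip(image, 0.0, None).mean(axis=axis)
    if profile.max() <= 0:
        return False, float("nan"), 0.0
    peaks, props = find_peaks(profile, height=0.1 * profile.max())
    if peaks.size < 2:
        return False, float("nan"), 0.0
    order = np.argsort(props["peak_heights"])[::-1][:2]
    p1, p2 = sorted(peaks[order])
    valley = profile[p1 : p2 + 1].min()
    lower_peak = min(profile[p1], profile[p2])
    dip = 1.0 - valley / lower_peak
    sep = (_subpixel_peak(profile, p2) - _subpixel_peak(profile, p1)) * pixel_nm
    return bool(dip >= min_dip_fraction), float(sep), float(dip)


def fwhm(profile: np.ndarray, coords_nm: np.ndarray | None = None) -> float:
    """Linear-interpolated full width at half maximum of a single-peaked
    profile (coordinates default to unit spacing)."""
    profile = np.asarray(profile, dtype=float)
    if coords_nm is None:
        coords_nm = np.arange(profile.size, dtype=float)
    peaks, props = find_peaks(profile, prominence=0.3 * profile.max())
    if peaks.size > 1:
        raise ValueError(
            "profile has multiple peaks; use line_pair_resolved instead"
        )
    i = int(np.argmax(profile))
    half = profile[i] / 2.0
    left = right = None
    for j in range(i, 0, -1):
        if profile[j - 1] <= half:
            t = (half - profile[j - 1]) / (profile[j] - profile[j - 1])
            left = coords_nm[j - 1] + t * (coords_nm[j] - coords_nm[j - 1])
            break
    for j in range(i, profile.size - 1):
        if profile[j + 1] <= half:
            t = (profile[j] - half) / (profile[j] - profile[j + 1])
            right = coords_nm[j] + t * (coords_nm[j + 1] - coords_nm[j])
            break
    if left is None or right is None:
        raise ValueError("profile does not fall to half maximum on both sides")
    return float(right - left)
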