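"""Synthetic phantoms and the forward imaging model.

Generates 3D emitter scenes (microtubule-like filaments, surface-labeled
microspheres resting on the coverslip, line-pair resolution targets,
isolated beads) and renders them into multi-angle TIRF stacks and 9-frame
structured-illumination raw sets with additive Gaussian white noise at a
controlled signal-to-noise ratio.

Image formation is scalar: each emitter contributes
``brightness * I_exc(theta, z) * PSF(x - x0, y - y0)`` where the
excitation follows the evanescent decay of :mod:`maim.optics` and the
detection PSF is a normalized 2D Gaussian.  Azimuthal replicates of a
ring-TIRF stack therefore share the same noiseless image and differ only
in their noise realization, which is exactly the property azimuthal
averaging exploits downstream.

SNR convention: peak noiseless pixel over the whole stack divided by the
noise standard deviation.  Negative pixels produced by the additive noise
are kept; clipping is a display decision, not a data one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import make_interp_spline

from .optics import AngleGrid, OpticalConfig, evanescent_profile

__all__ = [
    "Scene",
    "NoiseModel",
    "MATIRFStack",
    "SIMRawSet",
    "SIMPattern",
    "make_microtubule_scene",
    "make_sphere_scene",
    "make_line_pair_scene",
    "make_point_scene",
    "default_psf_fwhm_nm",
    "render_matirf_stack",
    "render_sim_rawset",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SIM_ORIENTATIONS_DEG = (0.0, 60.0, 120.0)
SIM_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass(frozen=True)
class Scene:
    """A collection of point emitters in a lateral field.

    ``emitters`` is an (N, 4) float array of columns x_nm, y_nm, z_nm,
    brightness.  ``extent_nm`` is the (width, height) of the lateral
    field; emitters must lie inside it with z >= 0.
    """

    emitters: np.ndarray
    extent_nm: tuple[float, float]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.emitters, dtype=float).reshape(-1, 4)
        object.__setattr__(self, "emitters", e)
        if not np.all(np.isfinite(e)):
            raise ValueError("emitter coordinates must be finite")
        if np.any(e[:, 2] < 0):
            raise ValueError("emitter depth z must be non-negative")
        if np.any(e[:, 3] < 0):
            raise ValueError("emitter brightness must be non-negative")
        w, h = self.extent_nm
        if w <= 0 or h <= 0:
            raise ValueError("scene extent must be positive")
        if e.size and (
            np.any(e[:, 0] < 0)
            or np.any(e[:, 0] > w)
            or np.any(e[:, 1] < 0)
            or np.any(e[:, 1] > h)
        ):
            raise ValueError("emitters must lie inside the scene extent")

    @property
    def n(self) -> int:
        return self.emitters.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.emitters[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.emitters[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.emitters[:, 2]

    @property
    def brightness(self) -> np.ndarray:
        return self.emitters[:, 3]

    def union(self, other: "Scene") -> "Scene":
        if self.extent_nm != other.extent_nm:
            raise ValueError("scenes must share an extent to be combined")
        return Scene(
            np.vstack([self.emitters, other.emitters]),
            self.extent_nm,
            {"union": [self.provenance, other.provenance]},
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian white noise at a given peak-signal / sigma ratio."""

    snr: float
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is modeled")


@dataclass(frozen=True)
class SIMPattern:
    """Sinusoidal illumination pattern parameters for one raw set."""

    orientations_deg: tuple[float, ...]
    freq_cyc_per_nm: float
    phases: tuple[float, ...]
    modulation: float

    def k_vector(self, orientation_deg: float) -> np.ndarray:
        a = np.radians(orientation_deg)
        return self.freq_cyc_per_nm * np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class MATIRFStack:
    """Multi-angle TIRF image stack, angle-major / azimuth-minor frame order."""

    frames: np.ndarray  # (K * n_azimuth, ny, nx)
    angle_grid: AngleGrid
    config: OpticalConfig
    noise: NoiseModel | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if f.shape[0] != self.angle_grid.n_frames:
            raise ValueError(
                f"expected {self.angle_grid.n_frames} frames "
                f"(K={self.angle_grid.k} x n_azimuth={self.angle_grid.n_azimuth}), "
                f"got {f.shape[0]}"
            )

    def frames_by_angle(self) -> np.ndarray:
        """Frames reshaped to (K, n_azimuth, ny, nx)."""
        k, na = self.angle_grid.k, self.angle_grid.n_azimuth
        return self.frames.reshape(k, na, *self.frames.shape[1:])


@dataclass(frozen=True)
class SIMRawSet:
    """Nine structured-illumination raw frames: 3 orientations x 3 phases,
    orientation-major / phase-minor order."""

    frames: np.ndarray  # (9, ny, nx)
    pattern: SIMPattern
    config: OpticalConfig
    tirf_theta_deg: float
    noise: NoiseModel | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3 or f.shape[0] != 9:
            raise ValueError("a SIM raw set holds exactly 9 frames")
        if not 0 < self.pattern.modulation <= 1:
            raise ValueError("modulation depth must lie in (0, 1]")

    def frame(self, orientation: int, phase: int) -> np.ndarray:
        return self.frames[3 * orientation + phase]

    def widefield(self) -> np.ndarray:
        """Mean of the 9 frames: pattern phases cancel, leaving the
        diffraction-limited TIRF image."""
        return self.frames.mean(axis=0)


def default_psf_fwhm_nm(config: OpticalConfig) -> float:
    """Detection PSF FWHM: Abbe limit lambda_em / (2 NA) at the emission
    wavelength."""
    return config.emission_wavelength_nm / (2.0 * config.na)


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------


def make_microtubule_scene(
    n_filaments: int,
    extent_nm: float | tuple[float, float] = 13312.0,
    z_range_nm: tuple[float, float] = (0.0, 400.0),
    seed: int = 0,
    spacing_nm: float = 20.0,
    jitter_nm: float = 25.0,
    brightness: float = 1.0,
) -> Scene:
    """Random smooth 3D filaments sampled as dense beads.

    Each filament is a cubic-spline-smoothed random walk across the field,
    sampled every ``spacing_nm`` along its arc with Gaussian lateral
    jitter of ``jitter_nm`` (the apparent filament radius).  Depth varies
    smoothly along the filament within ``z_range_nm``.
    """
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    if np.isscalar(extent_nm):
        extent = (float(extent_nm), float(extent_nm))
    else:
        extent = (float(extent_nm[0]), float(extent_nm[1]))
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError("scene extent must be positive")
    z_lo, z_hi = float(z_range_nm[0]), float(z_range_nm[1])
    if z_lo < 0 or z_hi < z_lo:
        raise ValueError("invalid z range")
    rng = np.random.default_rng(seed)
    pts = []
    n_ctrl = 8
    for _ in range(n_filaments):
        # control polygon: start on one edge, drift across the field
        ctrl = np.empty((n_ctrl, 2))
        ctrl[0] = rng.uniform(0, 1, 2) * extent
        heading = rng.uniform(0, 2 * np.pi)
        step = max(extent) / (n_ctrl - 1)
        for i in range(1, n_ctrl):
            heading += rng.normal(0, 0.5)
            ctrl[i] = ctrl[i - 1] + step * np.array(
                [np.cos(heading), np.sin(heading)]
            )
        t = np.linspace(0, 1, n_ctrl)
        spline = make_interp_spline(t, ctrl, k=3)
        dense = spline(np.linspace(0, 1, 600))
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        n_beads = max(int(arc[-1] / spacing_nm), 2)
        s = np.linspace(0, arc[-1], n_beads)
        xy = np.column_stack(
            [np.interp(s, arc, dense[:, 0]), np.interp(s, arc, dense[:, 1])]
        )
        xy += rng.normal(0, jitter_nm, xy.shape)
        # smooth axial course within the requested band
        z_ctrl = rng.uniform(z_lo, z_hi, n_ctrl)
        if z_hi > z_lo:
            z_vals = make_interp_spline(t, z_ctrl, k=3)(s / max(arc[-1], 1e-9))
            z_vals = np.clip(z_vals, z_lo, z_hi)
        else:
            z_vals = np.full(n_beads, z_lo)
        keep = (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= extent[0])
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= extent[1])
        )
        pts.append(
            np.column_stack(
                [xy[keep], z_vals[keep], np.full(keep.sum(), brightness)]
            )
        )
    emitters = np.vstack(pts) if pts else np.empty((0, 4))
    return Scene(
        emitters,
        extent,
        provenance={
            "generator": "microtubule",
            "n_filaments": n_filaments,
            "z_range_nm": (z_lo, z_hi),
            "spacing_nm": spacing_nm,
            "jitter_nm": jitter_nm,
            "seed": seed,
        },
    )


def make_sphere_scene(
    diameter_um: float = 4.86,
    extent_nm: float | tuple[float, float] = 4160.0,
    surface_density_per_um2: float = 300.0,
    z_cap_max_nm: float = 550.0,
    seed: int = 0,
    brightness: float = 1.0,
) -> Scene:
    """Surface-labeled microsphere resting on the coverslip.

    Emitters are uniform on the lower spherical cap that touches z = 0 at
    the contact point; only the cap with z(r) = R - sqrt(R^2 - r^2) up to
    ``z_cap_max_nm`` is populated (deeper labels contribute no evanescent
    signal).  The sphere is centered laterally in the field.
    """
    if diameter_um <= 0:
        raise ValueError("sphere diameter must be positive")
    if np.isscalar(extent_nm):
        extent = (float(extent_nm), float(extent_nm))
    else:
        extent = (float(extent_nm[0]), float(extent_nm[1]))
    r_nm = diameter_um * 1000.0 / 2.0
    z_cap = float(z_cap_max_nm)
    if z_cap > r_nm:
        import warnings

        warnings.warn("z_cap_max exceeds the sphere radius; clipping to R")
        z_cap = r_nm
    rng = np.random.default_rng(seed)
    cap_area_um2 = 2.0 * np.pi * r_nm * z_cap * 1e-6
    n = rng.poisson(surface_density_per_um2 * cap_area_um2)
    # uniform over the cap: cos of the polar angle from the bottom pole is
    # uniform on [1 - z_cap/R, 1]
    u = rng.uniform(1.0 - z_cap / r_nm, 1.0, n)
    z = r_nm * (1.0 - u)
    rho = r_nm * np.sqrt(1.0 - u**2)
    phi = rng.uniform(0, 2 * np.pi, n)
    cx, cy = extent[0] / 2.0, extent[1] / 2.0
    x = cx + rho * np.cos(phi)
    y = cy + rho * np.sin(phi)
    keep = (x >= 0) & (x <= extent[0]) & (y >= 0) & (y <= extent[1])
    emitters = np.column_stack(
        [x[keep], y[keep], z[keep], np.full(keep.sum(), brightness)]
    )
    return Scene(
        emitters,
        extent,
        provenance={
            "generator": "sphere",
            "diameter_um": diameter_um,
            "radius_nm": r_nm,
            "center_nm": (cx, cy),
            "z_cap_max_nm": z_cap,
            "surface_density_per_um2": surface_density_per_um2,
            "seed": seed,
        },
    )


def make_line_pair_scene(
    separation_nm: float,
    extent_nm: float | tuple[float, float] = 6656.0,
    z_nm: float = 0.0,
    seed: int = 0,
    spacing_nm: float = 10.0,
    brightness: float = 1.0,
) -> Scene:
    """Two parallel dense emitter lines (along y) at a given lateral
    separation and constant depth; ``separation_nm = 0`` degenerates to a
    single line."""
    if separation_nm < 0:
        raise ValueError("separation must be non-negative")
    if np.isscalar(extent_nm):
        extent = (float(extent_nm), float(extent_nm))
    else:
        extent = (float(extent_nm[0]), float(extent_nm[1]))
    cx = extent[0] / 2.0
    y = np.arange(0.1 * extent[1], 0.9 * extent[1], spacing_nm)
    xs = [cx - separation_nm / 2.0, cx + separation_nm / 2.0]
    if separation_nm == 0:
        xs = [cx]
    rows = []
    for x0 in xs:
        rows.append(
            np.column_stack(
                [
                    np.full(y.size, x0),
                    y,
                    np.full(y.size, float(z_nm)),
                    np.full(y.size, brightness),
                ]
            )
        )
    return Scene(
        np.vstack(rows),
        extent,
        provenance={
            "generator": "line_pair",
            "separation_nm": separation_nm,
            "z_nm": z_nm,
            "seed": seed,
        },
    )


def make_point_scene(
    z_nm: float = 0.0,
    extent_nm: float | tuple[float, float] = 1664.0,
    brightness: float = 1.0,
) -> Scene:
    """A single emitter at the center of the field, at depth ``z_nm``."""
    if np.isscalar(extent_nm):
        extent = (float(extent_nm), float(extent_nm))
    else:
        extent = (float(extent_nm[0]), float(extent_nm[1]))
    return Scene(
        np.array([[extent[0] / 2.0, extent[1] / 2.0, float(z_nm), brightness]]),
        extent,
        provenance={"generator": "point", "z_nm": z_nm},
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _grid_shape(scene: Scene, pixel_nm: float) -> tuple[int, int]:
    nx = int(round(scene.extent_nm[0] / pixel_nm))
    ny = int(round(scene.extent_nm[1] / pixel_nm))
    return ny, nx


def _splat_gaussians(
    scene: Scene,
    weights: np.ndarray,
    shape: tuple[int, int],
    pixel_nm: float,
    sigma_nm: float,
) -> np.ndarray:
    """Accumulate weighted 2D Gaussians at exact emitter positions.

    Evaluates each emitter's Gaussian on a local window of pixels (out to
    4 sigma) at the true sub-pixel position; the amplitude is normalized
    so each unit-weight emitter integrates to one over the pixel grid.
    Pixel (row, col) is centered at ((col + 0.5) px, (row + 0.5) px).
    """
    ny, nx = shape
    img = np.zeros((ny, nx))
    if scene.n == 0:
        return img
    sig_px = sigma_nm / pixel_nm
    half = max(int(np.ceil(4.0 * sig_px)), 2)
    # emitter positions in pixel units
    px = scene.x / pixel_nm - 0.5
    py = scene.y / pixel_nm - 0.5
    cx = np.round(px).astype(int)
    cy = np.round(py).astype(int)
    offs = np.arange(-half, half + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    ox = ox.ravel()
    oy = oy.ravel()
    cols = cx[:, None] + ox[None, :]
    rows = cy[:, None] + oy[None, :]
    dx = cols - px[:, None]
    dy = rows - py[:, None]
    g = np.exp(-(dx**2 + dy**2) / (2.0 * sig_px**2))
    g /= 2.0 * np.pi * sig_px**2
    vals = weights[:, None] * g
    inside = (cols >= 0) & (cols < nx) & (rows >= 0) & (rows < ny)
    np.add.at(img, (rows[inside], cols[inside]), vals[inside])
    return img


def _add_noise(
    frames: np.ndarray, noise: NoiseModel | None
) -> tuple[np.ndarray, float]:
    if noise is None:
        return frames, 0.0
    peak = float(frames.max())
    if peak <= 0:
        return frames, 0.0
    sigma = peak / noise.snr
    rng = np.random.default_rng(noise.seed)
    return frames + rng.normal(0.0, sigma, frames.shape), sigma


def render_matirf_stack(
    scene: Scene,
    angle_grid: AngleGrid,
    config: OpticalConfig,
    noise: NoiseModel | None = None,
    psf_fwhm_nm: float | None = None,
    intensity_model: str = "fresnel",
) -> MATIRFStack:
    """Render a scene into a multi-angle TIRF stack.

    Per polar angle, every emitter is excited by the evanescent field
    I(theta, z) and imaged through the Gaussian detection PSF; azimuthal
    replicates share the noiseless image and receive independent noise.
    The noise sigma is (peak noiseless pixel over all frames) / snr.
    """
    angle_grid.validate_supercritical(config)
    if psf_fwhm_nm is None:
        psf_fwhm_nm = default_psf_fwhm_nm(config)
    sigma_nm = psf_fwhm_nm * FWHM_TO_SIGMA
    shape = _grid_shape(scene, config.pixel_nm)
    base = np.empty((angle_grid.k, *shape))
    for i, theta in enumerate(angle_grid.theta_deg):
        exc = evanescent_profile(theta, scene.z, config, model=intensity_model)
        base[i] = _splat_gaussians(
            scene, scene.brightness * exc, shape, config.pixel_nm, sigma_nm
        )
    frames = np.repeat(base, angle_grid.n_azimuth, axis=0)
    frames, sigma = _add_noise(frames, noise)
    return MATIRFStack(
        frames=frames,
        angle_grid=angle_grid,
        config=config,
        noise=noise,
        meta={
            "psf_fwhm_nm": psf_fwhm_nm,
            "intensity_model": intensity_model,
            "noise_sigma": sigma,
            "scene": scene.provenance,
        },
    )


def render_sim_rawset(
    scene: Scene,
    config: OpticalConfig,
    pattern_freq_fraction: float = 0.9,
    modulation: float = 0.9,
    tirf_theta_deg: float = 62.0,
    noise: NoiseModel | None = None,
    psf_fwhm_nm: float | None = None,
    intensity_model: str = "fresnel",
    orientations_deg: tuple[float, float, float] = SIM_ORIENTATIONS_DEG,
) -> SIMRawSet:
    """Render the nine TIRF-SIM raw frames of a scene.

    The illumination is the evanescent excitation at ``tirf_theta_deg``
    modulated by a sinusoid, 1 + m cos(2 pi k.r + phi), with three pattern
    orientations (0/60/120 deg) times three phases (0, 2pi/3, 4pi/3).
    ``pattern_freq_fraction`` sets |k| as a fraction of the detection
    cutoff 2 NA / lambda_em.
    """
    if not 0 < pattern_freq_fraction <= 1:
        raise ValueError("pattern frequency fraction must lie in (0, 1]")
    if not 0 < modulation <= 1:
        raise ValueError("modulation depth must lie in (0, 1]")
    if psf_fwhm_nm is None:
        psf_fwhm_nm = default_psf_fwhm_nm(config)
    sigma_nm = psf_fwhm_nm * FWHM_TO_SIGMA
    shape = _grid_shape(scene, config.pixel_nm)
    freq = pattern_freq_fraction * config.detection_cutoff
    pattern = SIMPattern(
        orientations_deg=tuple(orientations_deg),
        freq_cyc_per_nm=freq,
        phases=SIM_PHASES,
        modulation=modulation,
    )
    exc = evanescent_profile(
        tirf_theta_deg, scene.z, config, model=intensity_model
    )
    frames = np.empty((9, *shape))
    for o, orient in enumerate(pattern.orientations_deg):
        kvec = pattern.k_vector(orient)
        phase_arg = 2.0 * np.pi * (kvec[0] * scene.x + kvec[1] * scene.y)
        for p, phi in enumerate(pattern.phases):
            illum = 1.0 + modulation * np.cos(phase_arg + phi)
            frames[3 * o + p] = _splat_gaussians(
                scene,
                scene.brightness * exc * illum,
                shape,
                config.pixel_nm,
                sigma_nm,
            )
    frames, sigma = _add_noise(frames, noise)
    return SIMRawSet(
        frames=frames,
        pattern=pattern,
        config=config,
        tirf_theta_deg=tirf_theta_deg,
        noise=noise,
        meta={
            "psf_fwhm_nm": psf_fwhm_nm,
            "intensity_model": intensity_model,
            "noise_sigma": sigma,
            "scene": scene.provenance,
        },
    )
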