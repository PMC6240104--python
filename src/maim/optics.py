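"""Evanescent-field physics for variable-angle TIRF.

Closed-form model of the evanescent wave generated by total internal
reflection at a coverslip--sample interface: critical angle, penetration
depth, interface intensity, and the discretized angle x depth system
matrix that links an axial fluorophore distribution to the per-angle
detected signal.

Conventions: angles cross the public API in degrees and are converted to
radians internally; depths are in nanometers with z = 0 at the
coverslip--sample interface, increasing into the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "AngleGrid",
    "AxialGrid",
    "SystemMatrix",
    "critical_angle",
    "penetration_depth",
    "interface_intensity",
    "evanescent_profile",
    "build_system_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OpticalConfig:
    """Physical constants shared by every pipeline stage.

    Parameters
    ----------
    wavelength_nm : float
        Vacuum excitation wavelength (nm).
    na : float
        Objective numerical aperture.
    n1 : float
        Refractive index on the illumination side (immersion oil /
        coverslip). Default 1.518, standard oil for an NA 1.49 TIRF
        objective.
    n2 : float
        Sample-medium refractive index. Default 1.33 (aqueous buffer);
        should be overridden with the measured value for each sample.
    pixel_nm : float
        Raw-image pixel size in sample space (nm).
    """

    wavelength_nm: float = 488.0
    na: float = 1.49
    n1: float = 1.518
    n2: float = 1.33
    pixel_nm: float = 52.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if not self.n2 < self.n1:
            raise ValueError(
                "total internal reflection requires n2 < n1 "
                f"(got n1={self.n1}, n2={self.n2})"
            )
        if self.na > self.n1:
            raise ValueError("numerical aperture cannot exceed n1")

    @property
    def critical_angle_deg(self) -> float:
        return critical_angle(self.n1, self.n2)

    @property
    def emission_wavelength_nm(self) -> float:
        """Detection wavelength: excitation plus a 20 nm Stokes shift."""
        return self.wavelength_nm + 20.0

    @property
    def detection_cutoff(self) -> float:
        """Incoherent detection OTF cutoff 2*NA/lambda_em (cycles/nm)."""
        return 2.0 * self.na / self.emission_wavelength_nm


@dataclass(frozen=True)
class AngleGrid:
    """Ordered polar incidence angles with optional azimuthal replication.

    ``theta_deg`` must be strictly increasing and every angle supercritical
    for the optical configuration it is used with.  ``n_azimuth`` is the
    number of azimuthal beam directions recorded per polar angle
    (ring-TIRF averaging).
    """

    theta_deg: tuple[float, ...]
    n_azimuth: int = 1

    def __init__(self, theta_deg, n_azimuth: int = 1):
        theta = tuple(float(t) for t in np.atleast_1d(theta_deg))
        if len(theta) < 1:
            raise ValueError("angle grid is empty")
        if any(b <= a for a, b in zip(theta, theta[1:])):
            raise ValueError("theta_deg must be strictly increasing")
        if int(n_azimuth) < 1:
            raise ValueError("n_azimuth must be >= 1")
        object.__setattr__(self, "theta_deg", theta)
        object.__setattr__(self, "n_azimuth", int(n_azimuth))

    @classmethod
    def from_start_step(
        cls, start_deg: float, step_deg: float, count: int, n_azimuth: int = 1
    ) -> "AngleGrid":
        theta = start_deg + step_deg * np.arange(count)
        return cls(theta, n_azimuth)

    @property
    def k(self) -> int:
        return len(self.theta_deg)

    @property
    def n_frames(self) -> int:
        return self.k * self.n_azimuth

    def validate_supercritical(self, config: OpticalConfig) -> None:
        theta_c = config.critical_angle_deg
        bad = [t for t in self.theta_deg if t <= theta_c]
        if bad:
            raise ValueError(
                f"angles {bad} do not exceed the critical angle "
                f"{theta_c:.3f} deg for n1={config.n1}, n2={config.n2}"
            )


@dataclass(frozen=True)
class AxialGrid:
    """Uniform depth bins, z = 0 at the coverslip."""

    z_nm: np.ndarray
    bin_nm: float

    def __init__(self, z_nm=None, bin_nm: float | None = None):
        if z_nm is None:
            z_nm = np.arange(0.0, 600.0 + 1e-9, 10.0)
        z = np.asarray(z_nm, dtype=float)
        if z.ndim != 1 or z.size < 1:
            raise ValueError("z_nm must be a 1-D array")
        if z[0] < 0:
            raise ValueError("depth bins must start at z >= 0")
        if z.size > 1:
            steps = np.diff(z)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("z_nm must be uniformly increasing")
            inferred = float(steps[0])
        else:
            inferred = float(bin_nm) if bin_nm is not None else 1.0
        object.__setattr__(self, "z_nm", z)
        object.__setattr__(
            self, "bin_nm", float(bin_nm) if bin_nm is not None else inferred
        )

    @classmethod
    def from_range(cls, z_max_nm: float = 600.0, z_step_nm: float = 10.0) -> "AxialGrid":
        return cls(np.arange(0.0, z_max_nm + z_step_nm / 2, z_step_nm), z_step_nm)

    @property
    def m(self) -> int:
        return int(self.z_nm.size)


def critical_angle(n1: float, n2: float) -> float:
    """Critical angle of total internal reflection, arcsin(n2/n1), degrees.

    Raises
    ------
    ValueError
        If ``n2 >= n1`` (no total internal reflection possible).
    """
    if not 0 < n2 < n1:
        raise ValueError(
            f"no total internal reflection possible for n1={n1}, n2={n2}"
        )
    return float(np.degrees(np.arcsin(n2 / n1)))


def _check_supercritical(theta_deg, config: OpticalConfig) -> np.ndarray:
    theta = np.asarray(theta_deg, dtype=float)
    theta_c = config.critical_angle_deg
    if np.any(theta <= theta_c):
        raise ValueError(
            f"incidence angle must exceed the critical angle {theta_c:.3f} deg"
        )
    if np.any(theta >= 90.0):
        raise ValueError("incidence angle must be below 90 deg")
    return theta


def penetration_depth(theta_deg, config: OpticalConfig):
    """Evanescent-field penetration depth d(theta) in nm.

    d = lambda / (4 pi sqrt(n1^2 sin^2 theta - n2^2)); the depth at which
    the evanescent intensity has decayed to 1/e.  Strictly decreasing in
    theta and divergent as theta approaches the critical angle from above.
    """
    theta = _check_supercritical(theta_deg, config)
    rad = np.radians(theta)
    root = np.sqrt((config.n1 * np.sin(rad)) ** 2 - config.n2**2)
    d = config.wavelength_nm / (4.0 * np.pi * root)
    return float(d) if np.isscalar(theta_deg) else d


def interface_intensity(theta_deg, config: OpticalConfig, model: str = "fresnel"):
    """Evanescent intensity at z = 0 relative to the incident intensity.

    ``model='fresnel'`` uses the s-polarized Fresnel transmission
    I0 = 4 cos^2(theta) / (1 - (n2/n1)^2), which equals 4 exactly at the
    critical angle and falls to 0 at grazing incidence.  ``model='unit'``
    returns 1 for every angle (excitation strength treated as unknown and
    absorbed into the reconstruction).
    """
    theta = _check_supercritical(theta_deg, config)
    if model == "unit":
        out = np.ones_like(np.asarray(theta, dtype=float))
    elif model == "fresnel":
        rad = np.radians(theta)
        out = 4.0 * np.cos(rad) ** 2 / (1.0 - (config.n2 / config.n1) ** 2)
    else:
        raise ValueError(f"unknown intensity model {model!r}")
    return float(out) if np.isscalar(theta_deg) else out


def evanescent_profile(theta_deg, z_nm, config: OpticalConfig, model: str = "fresnel"):
    """Evanescent excitation intensity I(theta, z) = I0(theta) exp(-z/d(theta))."""
    z = np.asarray(z_nm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be non-negative")
    i0 = interface_intensity(theta_deg, config, model=model)
    d = penetration_depth(theta_deg, config)
    out = np.asarray(i0) * np.exp(-z / np.asarray(d))
    if np.isscalar(theta_deg) and np.isscalar(z_nm):
        return float(out)
    return out


@dataclass(frozen=True)
class SystemMatrix:
    """K x M forward model: A[k, m] = I0(theta_k) exp(-z_m / d(theta_k)).

    Rows are incidence angles, columns are depth bins.  Every entry is
    positive; each row decays strictly along depth, and the relative
    response at depth, A[k, m] / A[k, 0], decreases with increasing angle
    (steeper angles probe shallower).
    """

    a: np.ndarray
    angle_grid: AngleGrid
    axial_grid: AxialGrid
    config: OpticalConfig
    intensity_model: str = "fresnel"
    normalized: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    def validate(self) -> None:
        a = self.a
        if not np.all(a > 0):
            raise AssertionError("system matrix entries must be positive")
        if self.axial_grid.m > 1 and not np.all(np.diff(a, axis=1) < 0):
            raise AssertionError("rows must decrease strictly along depth")
        if self.angle_grid.k > 1 and self.axial_grid.m > 1:
            rel = a[:, 1:] / a[:, :1]
            if not np.all(np.diff(rel, axis=0) < 0):
                raise AssertionError(
                    "relative depth response must decrease with angle"
                )


def build_system_matrix(
    angle_grid: AngleGrid,
    axial_grid: AxialGrid,
    config: OpticalConfig,
    intensity_model: str = "fresnel",
    normalized: bool = False,
) -> SystemMatrix:
    """Discretize the evanescent forward model on an angle x depth grid.

    With ``normalized=True`` the matrix is globally rescaled so the largest
    interface (z = 0) response equals one, which makes the regularization
    weight of the depth solver scale-free.
    """
    angle_grid.validate_supercritical(config)
    theta = np.asarray(angle_grid.theta_deg)
    i0 = interface_intensity(theta, config, model=intensity_model)
    d = penetration_depth(theta, config)
    a = i0[:, None] * np.exp(-axial_grid.z_nm[None, :] / d[:, None])
    if normalized:
        a = a / a[:, 0].max()
    mat = SystemMatrix(
        a=a,
        angle_grid=angle_grid,
        axial_grid=axial_grid,
        config=config,
        intensity_model=intensity_model,
        normalized=normalized,
    )
    mat.validate()
    log.info(
        "system matrix %dx%d, cond=%.3g",
        a.shape[0],
        a.shape[1],
        np.linalg.cond(a),
    )
    return mat
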