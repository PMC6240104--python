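"""Run configuration: one YAML/JSON block that fixes every tunable of a
pipeline run and can be hashed into output provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .depth import SolverParams
from .optics import AngleGrid, AxialGrid, OpticalConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Angles may be given either as an explicit list (``angles``) or as
    ``angle_start / angle_step / angle_count``.
    """

    wavelength_nm: float = 488.0
    na: float = 1.49
    n1: float = 1.518
    n2: float = 1.33
    pixel_nm: float = 52.0
    angles: list[float] | None = None
    angle_start: float = 61.5
    angle_step: float = 0.5
    angle_count: int = 20
    n_azimuth: int = 1
    z_max_nm: float = 600.0
    z_step_nm: float = 10.0
    intensity_model: str = "fresnel"
    wiener_w: float = 0.1
    mask_method: str = "otsu"
    mask_threshold: float | None = None
    background_window_px: int = 32
    solver: str = "admm"
    mu: float = 0.01
    rho: float = 1.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def optical(self) -> OpticalConfig:
        return OpticalConfig(
            wavelength_nm=self.wavelength_nm,
            na=self.na,
            n1=self.n1,
            n2=self.n2,
            pixel_nm=self.pixel_nm,
        )

    def angle_grid(self) -> AngleGrid:
        if self.angles is not None:
            return AngleGrid(self.angles, self.n_azimuth)
        return AngleGrid.from_start_step(
            self.angle_start, self.angle_step, self.angle_count, self.n_azimuth
        )

    def axial_grid(self) -> AxialGrid:
        return AxialGrid.from_range(self.z_max_nm, self.z_step_nm)

    def solver_params(self) -> SolverParams:
        return SolverParams(
            mu=self.mu,
            rho=self.rho,
            max_iter=self.max_iter,
            tol=self.tol,
            solver=self.solver,
        )

    def validate(self) -> "RunConfig":
        # constructing the domain objects runs every invariant check
        cfg = self.optical()
        self.angle_grid().validate_supercritical(cfg)
        self.axial_grid()
        self.solver_params()
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in d.items() if k not in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
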