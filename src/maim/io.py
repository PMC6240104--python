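"""Reading and writing stacks, images, scenes, and reports.

All image data travel as multi-page 32-bit float TIFF with a JSON
sidecar carrying the acquisition metadata (angles, azimuths, pattern
parameters, optical configuration, noise seed).  Frame order follows the
acquisition sequence: angle-major / azimuth-minor for multi-angle
stacks, orientation-major / phase-minor for SIM raw sets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .depth import DepthMap
from .optics import AngleGrid, OpticalConfig
from .phantoms import (
    MATIRFStack,
    NoiseModel,
    Scene,
    SIMPattern,
    SIMRawSet,
)
from .simrecon import SRImage

__all__ = [
    "write_stack",
    "read_stack",
    "write_sr_image",
    "write_depth_map",
    "scene_to_csv",
    "scene_from_csv",
    "provenance_hash",
]


def provenance_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable metadata object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _config_dict(config: OpticalConfig) -> dict[str, float]:
    return {
        "wavelength_nm": config.wavelength_nm,
        "na": config.na,
        "n1": config.n1,
        "n2": config.n2,
        "pixel_nm": config.pixel_nm,
    }


def _noise_dict(noise: NoiseModel | None) -> dict[str, Any] | None:
    if noise is None:
        return None
    return {"kind": noise.kind, "snr": noise.snr, "seed": noise.seed}


def write_stack(stack: MATIRFStack | SIMRawSet, path: str | Path) -> Path:
    """Write a stack as multi-page float32 TIFF plus JSON sidecar.

    Returns the TIFF path; the sidecar sits next to it with the same stem.
    """
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(stack, MATIRFStack):
        meta: dict[str, Any] = {
            "kind": "matirf",
            "theta_deg": list(stack.angle_grid.theta_deg),
            "n_azimuth": stack.angle_grid.n_azimuth,
            "config": _config_dict(stack.config),
            "noise": _noise_dict(stack.noise),
            "extra": stack.meta,
        }
    elif isinstance(stack, SIMRawSet):
        meta = {
            "kind": "simraw",
            "pattern": {
                "orientations_deg": list(stack.pattern.orientations_deg),
                "freq_cyc_per_nm": stack.pattern.freq_cyc_per_nm,
                "phases": list(stack.pattern.phases),
                "modulation": stack.pattern.modulation,
            },
            "tirf_theta_deg": stack.tirf_theta_deg,
            "config": _config_dict(stack.config),
            "noise": _noise_dict(stack.noise),
            "extra": stack.meta,
        }
    else:
        raise TypeError(f"cannot write {type(stack).__name__}")
    meta["n_frames"] = int(stack.frames.shape[0])
    meta["provenance_hash"] = provenance_hash(
        {k: v for k, v in meta.items() if k != "extra"}
    )
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_stack(path: str | Path) -> MATIRFStack | SIMRawSet:
    """Read a stack written by :func:`write_stack`, validating the frame
    count against the sidecar."""
    path = Path(path).with_suffix(".tif")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    frames = np.atleast_3d(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"sidecar lists {meta['n_frames']} frames but the TIFF holds "
            f"{frames.shape[0]} pages"
        )
    config = OpticalConfig(**meta["config"])
    noise = NoiseModel(**meta["noise"]) if meta.get("noise") else None
    if meta["kind"] == "matirf":
        grid = AngleGrid(meta["theta_deg"], meta["n_azimuth"])
        return MATIRFStack(
            frames=frames.astype(float),
            angle_grid=grid,
            config=config,
            noise=noise,
            meta=meta.get("extra", {}),
        )
    if meta["kind"] == "simraw":
        p = meta["pattern"]
        pattern = SIMPattern(
            orientations_deg=tuple(p["orientations_deg"]),
            freq_cyc_per_nm=p["freq_cyc_per_nm"],
            phases=tuple(p["phases"]),
            modulation=p["modulation"],
        )
        return SIMRawSet(
            frames=frames.astype(float),
            pattern=pattern,
            config=config,
            tirf_theta_deg=meta["tirf_theta_deg"],
            noise=noise,
            meta=meta.get("extra", {}),
        )
    raise ValueError(f"unknown stack kind {meta['kind']!r}")


def write_sr_image(sr: SRImage, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, sr.image.astype(np.float32))
    meta = {
        "kind": "sr_image",
        "pixel_nm": sr.pixel_nm,
        "effective_cutoff": sr.effective_cutoff,
        "provenance": sr.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def write_depth_map(depth_map: DepthMap, base: str | Path) -> dict[str, Path]:
    """Write the depth map as float32 TIFFs (h, intensity, mask, optional
    volume slices) plus a JSON solver report."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    out["h"] = base.with_name(base.name + "_h.tif")
    tifffile.imwrite(out["h"], depth_map.h.astype(np.float32))
    out["intensity"] = base.with_name(base.name + "_intensity.tif")
    tifffile.imwrite(out["intensity"], depth_map.intensity.astype(np.float32))
    out["mask"] = base.with_name(base.name + "_mask.tif")
    tifffile.imwrite(
        out["mask"], (depth_map.mask.astype(np.uint8) * 255)
    )
    if depth_map.profiles is not None:
        from .depth import assemble_volume

        vol = assemble_volume(depth_map)
        out["volume"] = base.with_name(base.name + "_volume.tif")
        tifffile.imwrite(out["volume"], vol.astype(np.float32))
    report = {
        "z_nm": depth_map.axial_grid.z_nm.tolist(),
        "qc": depth_map.qc,
    }
    out["report"] = base.with_name(base.name + "_report.json")
    out["report"].write_text(json.dumps(report, indent=2, default=str))
    return out


def scene_to_csv(scene: Scene, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        scene.emitters, columns=["x_nm", "y_nm", "z_nm", "brightness"]
    )
    df.to_csv(path, index=False)
    meta = dict(scene.provenance)
    meta["extent_nm"] = list(scene.extent_nm)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def scene_from_csv(path: str | Path) -> Scene:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    extent = tuple(meta.pop("extent_nm", (df.x_nm.max(), df.y_nm.max())))
    return Scene(
        df[["x_nm", "y_nm", "z_nm", "brightness"]].to_numpy(),
        (float(extent[0]), float(extent[1])),
        provenance=meta,
    )
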