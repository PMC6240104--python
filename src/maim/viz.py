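"""Color-coded depth rendering.

The 3D result is displayed as a 2D RGB image in which hue encodes the
per-pixel mean depth and brightness encodes the integrated intensity —
the product of the intensity variation with the depth color.  Pixels
outside the mask are black.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from matplotlib import colormaps

from .depth import DepthMap

__all__ = ["DepthRendering", "render_depth"]


@dataclass(frozen=True)
class DepthRendering:
    rgb: np.ndarray  # (ny, nx, 3) floats in [0, 1]
    colormap: str
    z_range_nm: tuple[float, float]
    meta: dict[str, Any] = field(default_factory=dict)


def render_depth(
    depth_map: DepthMap,
    colormap: str = "viridis",
    z_range_nm: tuple[float, float] = (0.0, 600.0),
    intensity_percentile: float = 99.0,
) -> DepthRendering:
    """Map depth to color and scale by normalized intensity.

    ``colormap`` is any matplotlib colormap name; ``'jet'`` gives the
    classic rainbow depth look.  Intensity is normalized to the given
    percentile of the in-mask intensities and clipped to [0, 1].
    """
    z0, z1 = z_range_nm
    if not z1 > z0:
        raise ValueError("z_range must span a positive interval")
    cmap = colormaps[colormap]
    h = depth_map.h
    inten = depth_map.intensity
    valid = depth_map.mask & np.isfinite(h) & (inten > 0)
    frac = np.zeros_like(h)
    frac[valid] = np.clip((h[valid] - z0) / (z1 - z0), 0.0, 1.0)
    rgb = cmap(frac)[..., :3]
    if np.any(valid):
        norm = np.percentile(inten[valid], intensity_percentile)
    else:
        norm = 1.0
    bright = np.clip(inten / max(norm, 1e-300), 0.0, 1.0)
    bright[~valid] = 0.0
    rgb = rgb * bright[..., None]
    return DepthRendering(
        rgb=rgb,
        colormap=colormap,
        z_range_nm=(float(z0), float(z1)),
        meta={"intensity_percentile": intensity_percentile},
    )
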