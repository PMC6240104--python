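"""Preparation of the multi-angle stack for depth inversion.

The depth signal lives in the ratio of a pixel's intensities across
incidence angles, so everything that is not evanescent-excited signal —
camera offset, scattered light, out-of-focus haze — corrupts the
recovered depth.  This module averages azimuthal ring-TIRF replicates,
derives a binary mask from the lateral super-resolution image, estimates
and subtracts a local background from the off-mask pixels, and zeroes
everything outside the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce

from .optics import AngleGrid
from .phantoms import MATIRFStack
from .simrecon import SRImage

__all__ = [
    "BinaryMask",
    "SegmentedStack",
    "azimuthal_average",
    "make_mask",
    "subtract_background",
]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask on the raw pixel grid, derived from an SR image or
    supplied externally (e.g. by a trained segmentation tool)."""

    mask: np.ndarray
    threshold_value: float
    method: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentedStack:
    """Background-subtracted, masked multi-angle frames (one per angle)."""

    frames: np.ndarray  # (K, ny, nx)
    background: np.ndarray  # (K, ny, nx) estimated background maps
    mask: BinaryMask
    angle_grid: AngleGrid
    meta: dict[str, Any] = field(default_factory=dict)

    def pixel_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(K, P) matrix of in-mask pixel intensity vectors and the (P, 2)
        row/col indices, in row-major scan order."""
        rows, cols = np.nonzero(self.mask.mask)
        return self.frames[:, rows, cols], np.column_stack([rows, cols])


def azimuthal_average(stack: MATIRFStack) -> MATIRFStack:
    """Average ring-TIRF azimuthal replicates per polar angle.

    The scalar forward model is azimuth-independent, so averaging the
    replicates reduces the noise standard deviation by 1/sqrt(n_azimuth)
    without touching the depth-encoding angle ratios.
    """
    if stack.angle_grid.n_azimuth == 1:
        return stack
    by_angle = stack.frames_by_angle()
    mean = by_angle.mean(axis=1)
    grid = AngleGrid(stack.angle_grid.theta_deg, n_azimuth=1)
    meta = dict(stack.meta)
    meta["azimuthal_averaged_from"] = stack.angle_grid.n_azimuth
    return MATIRFStack(
        frames=mean,
        angle_grid=grid,
        config=stack.config,
        noise=stack.noise,
        meta=meta,
    )


def make_mask(
    sr_image: SRImage | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    raw_shape: tuple[int, int] | None = None,
) -> BinaryMask:
    """Threshold the SR image into a binary mask on the raw pixel grid.

    ``method='otsu'`` picks the threshold automatically from the SR
    histogram; ``method='fixed'`` uses ``threshold`` as a fraction of the
    image maximum.  The SR grid is twice as fine as the raw grid; a raw
    pixel is in-mask if any of its 2x2 SR pixels exceeds the threshold
    (conservative: keeps dim peripheral structure).
    """
    img = sr_image.image if isinstance(sr_image, SRImage) else np.asarray(sr_image)
    if not np.all(np.isfinite(img)):
        raise ValueError("SR image must be finite")
    pos = np.clip(img, 0.0, None)
    if pos.max() <= 0:
        warnings.warn("blank SR image: mask is empty")
        mask_sr = np.zeros_like(pos, dtype=bool)
        tval = 0.0
    elif method == "otsu":
        tval = float(threshold_otsu(pos))
        mask_sr = pos > tval
    elif method == "fixed":
        if threshold is None or not 0 < threshold < 1:
            raise ValueError("fixed method needs a threshold fraction in (0,1)")
        tval = float(threshold * pos.max())
        mask_sr = pos > tval
    else:
        raise ValueError(f"unknown mask method {method!r}")
    if raw_shape is None:
        if mask_sr.shape[0] % 2 or mask_sr.shape[1] % 2:
            raise ValueError("SR image shape must be even to downsample 2x")
        raw_shape = (mask_sr.shape[0] // 2, mask_sr.shape[1] // 2)
    if mask_sr.shape == raw_shape:
        mask = mask_sr
    else:
        mask = block_reduce(mask_sr, (2, 2), np.max).astype(bool)
    return BinaryMask(
        mask=mask,
        threshold_value=tval,
        method=method,
        source="sr_image",
    )


def _background_map(
    frame: np.ndarray, off_mask: np.ndarray, window_px: int
) -> np.ndarray:
    """Median of off-mask pixels on a coarse grid of window-sized
    neighborhoods, interpolated back to the full frame."""
    ny, nx = frame.shape
    step = max(window_px // 2, 1)
    half = window_px // 2
    cy = np.arange(half, ny, step)
    cx = np.arange(half, nx, step)
    if cy[-1] < ny - 1:
        cy = np.append(cy, ny - 1)
    if cx[-1] < nx - 1:
        cx = np.append(cx, nx - 1)
    if cy[0] > 0:
        cy = np.insert(cy, 0, 0)
    if cx[0] > 0:
        cx = np.insert(cx, 0, 0)
    grid = np.full((cy.size, cx.size), np.nan)
    for i, yy in enumerate(cy):
        y0, y1 = max(yy - half, 0), min(yy + half + 1, ny)
        for j, xx in enumerate(cx):
            x0, x1 = max(xx - half, 0), min(xx + half + 1, nx)
            sel = off_mask[y0:y1, x0:x1]
            if np.any(sel):
                grid[i, j] = np.median(frame[y0:y1, x0:x1][sel])
    if np.all(np.isnan(grid)):
        return np.full_like(frame, np.nan)
    # fill cells whose window held no off-mask pixel with the nearest value
    while np.any(np.isnan(grid)):
        nanmask = np.isnan(grid)
        padded = np.pad(grid, 1, mode="edge")
        neighbors = np.stack(
            [
                padded[:-2, 1:-1],
                padded[2:, 1:-1],
                padded[1:-1, :-2],
                padded[1:-1, 2:],
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmean(neighbors, axis=0)
        grid[nanmask] = fill[nanmask]
    interp = RegularGridInterpolator(
        (cy.astype(float), cx.astype(float)),
        grid,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    yy, xx = np.meshgrid(
        np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij"
    )
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(ny, nx)


def subtract_background(
    stack: MATIRFStack,
    mask: BinaryMask,
    window_px: int = 32,
    guard_px: int = 3,
) -> SegmentedStack:
    """Subtract a local background and segment the stack with the mask.

    Per frame, the background is the median of off-mask pixels in a
    sliding window (interpolated under the mask), subtracted everywhere;
    negatives are clamped to zero (the inverse problem needs non-negative
    data) and off-mask pixels are zeroed.  Background pixels are taken
    outside the mask dilated by ``guard_px`` (about one PSF radius), so
    the PSF halo of masked structure does not leak into the estimate.
    If the mask covers the whole frame there are no background pixels,
    and the global 1st percentile is used instead.
    """
    stack = azimuthal_average(stack)
    frames = stack.frames
    if mask.mask.shape != frames.shape[1:]:
        raise ValueError("mask shape does not match the frames")
    guarded = mask.mask
    if guard_px > 0:
        guarded = binary_dilation(mask.mask, iterations=guard_px)
    off = ~guarded
    if not np.any(off):
        off = ~mask.mask
    out = np.empty_like(frames)
    bg_maps = np.empty_like(frames)
    for k in range(frames.shape[0]):
        if not np.any(off):
            warnings.warn(
                "mask covers the entire frame; using global 1st-percentile "
                "background"
            )
            bg = np.full_like(frames[k], np.percentile(frames[k], 1.0))
        else:
            bg = _background_map(frames[k], off, window_px)
        bg_maps[k] = bg
        sub = np.clip(frames[k] - bg, 0.0, None)
        sub[off] = 0.0
        out[k] = sub
    return SegmentedStack(
        frames=out,
        background=bg_maps,
        mask=mask,
        angle_grid=stack.angle_grid,
        meta={"window_px": window_px, **stack.meta},
    )
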