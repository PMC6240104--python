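"""Azimuthal averaging, SR-derived masking, local background subtraction."""

import numpy as np
import pytest

from maim.optics import AngleGrid
from maim.phantoms import (
    MATIRFStack,
    NoiseModel,
    make_point_scene,
    render_matirf_stack,
)
from maim.segment import (
    BinaryMask,
    azimuthal_average,
    make_mask,
    subtract_background,
)

EXTENT = 64 * 52.0


def _stack(config, frames, n_azimuth=1, thetas=(63.0, 68.0)):
    grid = AngleGrid(list(thetas), n_azimuth)
    return MATIRFStack(frames=frames, angle_grid=grid, config=config)


class TestAzimuthalAverage:
    def test_identity_for_single_azimuth(self, config):
        frames = np.random.default_rng(0).uniform(0, 1, (2, 8, 8))
        stack = _stack(config, frames)
        assert azimuthal_average(stack) is stack

    def test_mean_of_constant_frames_is_exact(self, config):
        frames = np.full((8, 8, 8), 3.25)
        stack = _stack(config, frames, n_azimuth=4)
        out = azimuthal_average(stack)
        assert out.frames.shape == (2, 8, 8)
        assert np.all(out.frames == 3.25)

    def test_noise_reduction_scales_with_sqrt_n(self, config):
        # 4 azimuth replicates of one noiseless frame: averaging halves
        # the noise sigma
        grid = AngleGrid([63.0], n_azimuth=4)
        rng = np.random.default_rng(1)
        base = np.zeros((1, 128, 128))
        noisy = np.repeat(base, 4, axis=0) + rng.normal(0, 1.0, (4, 128, 128))
        stack = MATIRFStack(frames=noisy, angle_grid=grid, config=config)
        out = azimuthal_average(stack)
        assert out.frames[0].std() == pytest.approx(0.5, rel=0.1)


class TestMakeMask:
    def test_otsu_on_bimodal_image(self):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 100.0
        mask = make_mask(img, raw_shape=(8, 8))
        expect = np.zeros((8, 8), dtype=bool)
        expect[2:4, 2:4] = True
        assert np.array_equal(mask.mask, expect)

    def test_blank_image_warns_and_empties(self):
        with pytest.warns(UserWarning, match="blank"):
            mask = make_mask(np.zeros((16, 16)))
        assert mask.n_pixels == 0

    def test_fixed_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (32, 32))
        areas = [
            make_mask(img, method="fixed", threshold=t).n_pixels
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_downsampling_is_any_or(self):
        img = np.zeros((4, 4))
        img[1, 1] = 10.0  # one hot SR pixel within the 2x2 block
        img[0, 0] = 0.0
        mask = make_mask(img, method="fixed", threshold=0.5)
        assert mask.mask.shape == (2, 2)
        assert mask.mask[0, 0]
        assert mask.n_pixels == 1


class TestSubtractBackground:
    def test_constant_offset_recovered(self, config, angles20):
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        clean = render_matirf_stack(sc, angles20, config)
        offset = 0.07 * clean.frames.max()
        shifted = MATIRFStack(
            frames=clean.frames + offset,
            angle_grid=angles20,
            config=config,
        )
        mask = make_mask(clean.frames.max(axis=0), method="fixed", threshold=0.02,
                         raw_shape=clean.frames.shape[1:])
        seg = subtract_background(shifted, mask)
        m = mask.mask
        assert np.allclose(
            seg.frames[:, m], clean.frames[:, m], atol=0.02 * clean.frames.max()
        )

    def test_zero_background_identity_on_mask(self, config):
        frames = np.zeros((2, 32, 32))
        frames[:, 10:14, 10:14] = 5.0
        stack = _stack(config, frames)
        m = np.zeros((32, 32), dtype=bool)
        m[10:14, 10:14] = True
        seg = subtract_background(stack, BinaryMask(m, 0.0, "fixed"))
        assert np.allclose(seg.frames[:, m], 5.0, atol=1e-9)
        assert np.all(seg.frames[:, ~m] == 0.0)

    def test_pure_offset_frame_goes_to_zero(self, config):
        frames = np.full((2, 32, 32), 2.5)
        stack = _stack(config, frames)
        m = np.zeros((32, 32), dtype=bool)
        m[15:17, 15:17] = True
        seg = subtract_background(stack, BinaryMask(m, 0.0, "fixed"))
        assert np.allclose(seg.frames, 0.0, atol=1e-9)

    def test_idempotence(self, config, angles20):
        sc = make_point_scene(z_nm=100.0, extent_nm=EXTENT)
        stack = render_matirf_stack(
            sc, angles20, config, noise=NoiseModel(30.0, seed=3)
        )
        mask = make_mask(
            np.clip(stack.frames.mean(axis=0), 0, None),
            method="fixed",
            threshold=0.1,
            raw_shape=stack.frames.shape[1:],
        )
        seg1 = subtract_background(stack, mask)
        again = MATIRFStack(
            frames=seg1.frames, angle_grid=seg1.angle_grid, config=config
        )
        seg2 = subtract_background(again, mask)
        assert np.max(np.abs(seg2.frames - seg1.frames)) < 1e-9

    def test_full_mask_falls_back_to_percentile(self, config):
        frames = np.full((2, 16, 16), 4.0)
        stack = _stack(config, frames)
        m = np.ones((16, 16), dtype=bool)
        with pytest.warns(UserWarning, match="entire frame"):
            seg = subtract_background(stack, BinaryMask(m, 0.0, "fixed"))
        assert np.allclose(seg.frames, 0.0, atol=1e-12)

    def test_angle_order_of_peak_preserved(self, config, angles20):
        # background subtraction must not scramble the inter-angle
        # intensity ordering that encodes depth
        sc = make_point_scene(z_nm=150.0, extent_nm=EXTENT)
        clean = render_matirf_stack(sc, angles20, config)
        noisy = render_matirf_stack(
            sc, angles20, config, noise=NoiseModel(50.0, seed=7)
        )
        mask = make_mask(
            clean.frames.max(axis=0), method="fixed", threshold=0.05,
            raw_shape=clean.frames.shape[1:],
        )
        seg = subtract_background(noisy, mask)
        iy, ix = np.unravel_index(
            np.argmax(clean.frames[0]), clean.frames[0].shape
        )
        clean_order = np.argsort(clean.frames[:, iy, ix])
        seg_order = np.argsort(seg.frames[:, iy, ix])
        # allow neighbor swaps from noise; endpoints must agree
        assert clean_order[-1] == seg_order[-1]
        tau = np.corrcoef(clean_order, seg_order)[0, 1]
        assert tau > 0.9
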