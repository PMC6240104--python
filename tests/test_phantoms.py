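"""Phantom generators and the forward imaging model."""

import numpy as np
import pytest

from maim.optics import AngleGrid, OpticalConfig, evanescent_profile, penetration_depth
from maim.phantoms import (
    NoiseModel,
    Scene,
    make_line_pair_scene,
    make_microtubule_scene,
    make_point_scene,
    make_sphere_scene,
    render_matirf_stack,
    render_sim_rawset,
)

EXTENT = 64 * 52.0


class TestScenes:
    def test_scene_invariants(self):
        with pytest.raises(ValueError):
            Scene(np.array([[10.0, 10.0, -5.0, 1.0]]), (100.0, 100.0))
        with pytest.raises(ValueError):
            Scene(np.array([[500.0, 10.0, 0.0, 1.0]]), (100.0, 100.0))

    def test_microtubule_flat_range_and_determinism(self):
        sc = make_microtubule_scene(
            1, extent_nm=EXTENT, z_range_nm=(100.0, 100.0), seed=3
        )
        assert np.all(sc.z == 100.0)
        sc2 = make_microtubule_scene(
            5, extent_nm=EXTENT, z_range_nm=(0, 300), seed=7
        )
        sc3 = make_microtubule_scene(
            5, extent_nm=EXTENT, z_range_nm=(0, 300), seed=7
        )
        assert np.array_equal(sc2.emitters, sc3.emitters)

    def test_microtubule_bead_budget(self):
        # emitter count tracks total arc length / bead spacing
        sc = make_microtubule_scene(
            20, extent_nm=32000.0, z_range_nm=(0, 300), seed=1, spacing_nm=20.0
        )
        # each filament spans >= the field diagonal/2 worth of arc; beads
        # every 20 nm; clipping to the field loses some
        assert sc.n > 10000

    def test_sphere_geometry(self):
        sc = make_sphere_scene(4.86, extent_nm=4160.0, seed=2)
        r_nm = 2430.0
        cx, cy = sc.provenance["center_nm"]
        # every emitter lies on the sphere of radius R centered at
        # (cx, cy, R)
        lhs = (sc.x - cx) ** 2 + (sc.y - cy) ** 2 + (sc.z - r_nm) ** 2
        assert np.allclose(lhs, r_nm**2, rtol=1e-6)
        # z(r) = R - sqrt(R^2 - r^2): at r = 1000 nm, z = 215.3 nm
        assert r_nm - np.sqrt(r_nm**2 - 1000.0**2) == pytest.approx(215.3, abs=0.1)

    def test_sphere_cap_depth_limit(self):
        sc = make_sphere_scene(4.86, extent_nm=4160.0, z_cap_max_nm=300.0, seed=2)
        assert sc.z.max() <= 300.0

    def test_line_pair_separation(self):
        sc = make_line_pair_scene(100.0, extent_nm=EXTENT)
        xs = np.unique(sc.x)
        assert xs.size == 2
        assert xs[1] - xs[0] == pytest.approx(100.0)
        single = make_line_pair_scene(0.0, extent_nm=EXTENT)
        assert np.unique(single.x).size == 1


class TestMATIRFRendering:
    def test_peak_ratio_at_surface(self, config):
        # a z=0 emitter's per-angle peak ratio equals the interface
        # intensity ratio
        grid = AngleGrid([63.0, 68.0])
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        stack = render_matirf_stack(sc, grid, config)
        peaks = stack.frames.max(axis=(1, 2))
        expect = evanescent_profile(63.0, 0.0, config) / evanescent_profile(
            68.0, 0.0, config
        )
        assert peaks[0] / peaks[1] == pytest.approx(expect, rel=1e-9)

    def test_depth_attenuation_per_angle(self, config, angles20):
        sc0 = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        sc200 = make_point_scene(z_nm=200.0, extent_nm=EXTENT)
        s0 = render_matirf_stack(sc0, angles20, config)
        s200 = render_matirf_stack(sc200, angles20, config)
        ratio = s200.frames.max(axis=(1, 2)) / s0.frames.max(axis=(1, 2))
        d = penetration_depth(np.array(angles20.theta_deg), config)
        assert ratio == pytest.approx(np.exp(-200.0 / d), rel=1e-9)

    def test_noise_sigma_matches_snr(self, config):
        grid = AngleGrid.from_start_step(61.5, 0.5, 20)
        sc = make_point_scene(z_nm=0.0, extent_nm=128 * 52.0)
        clean = render_matirf_stack(sc, grid, config)
        noisy = render_matirf_stack(
            sc, grid, config, noise=NoiseModel(snr=30.0, seed=5)
        )
        resid = noisy.frames - clean.frames
        expect = clean.frames.max() / 30.0
        assert resid.std() == pytest.approx(expect, rel=0.05)

    def test_seeded_bit_reproducibility(self, config):
        grid = AngleGrid([63.0, 68.0], n_azimuth=2)
        sc = make_point_scene(z_nm=50.0, extent_nm=EXTENT)
        a = render_matirf_stack(sc, grid, config, noise=NoiseModel(30.0, seed=9))
        b = render_matirf_stack(sc, grid, config, noise=NoiseModel(30.0, seed=9))
        assert np.array_equal(a.frames, b.frames)

    def test_linearity_of_rendering(self, config):
        grid = AngleGrid([63.0, 68.0])
        rng = np.random.default_rng(0)
        def random_scene(seed):
            r = np.random.default_rng(seed)
            e = np.column_stack(
                [
                    r.uniform(200, EXTENT - 200, 30),
                    r.uniform(200, EXTENT - 200, 30),
                    r.uniform(0, 400, 30),
                    r.uniform(0.5, 2.0, 30),
                ]
            )
            return Scene(e, (EXTENT, EXTENT))
        a, b = random_scene(1), random_scene(2)
        union = a.union(b)
        fa = render_matirf_stack(a, grid, config).frames
        fb = render_matirf_stack(b, grid, config).frames
        fu = render_matirf_stack(union, grid, config).frames
        assert np.allclose(fu, fa + fb, rtol=1e-9, atol=1e-12)

    def test_azimuth_frames_share_noiseless_image(self, config):
        grid = AngleGrid([63.0, 68.0], n_azimuth=3)
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        stack = render_matirf_stack(sc, grid, config)
        by_angle = stack.frames_by_angle()
        for k in range(2):
            for a in range(1, 3):
                assert np.array_equal(by_angle[k, 0], by_angle[k, a])


class TestSIMRendering:
    def test_nine_frames(self, config):
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config)
        assert raw.frames.shape[0] == 9

    def test_zero_modulation_rejected(self, config):
        sc = make_point_scene(extent_nm=EXTENT)
        with pytest.raises(ValueError):
            render_sim_rawset(sc, config, modulation=0.0)
        with pytest.raises(ValueError):
            render_sim_rawset(sc, config, modulation=1.5)

    def test_small_modulation_approaches_uniform(self, config):
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config, modulation=1e-6)
        spread = raw.frames.max(axis=0) - raw.frames.min(axis=0)
        assert spread.max() <= 1e-5 * raw.frames.max()

    def test_phase_sum_cancels_pattern(self, config):
        # sum of the 3 phase frames per orientation is 3x the uniform image
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config, modulation=0.9)
        uniform = render_sim_rawset(sc, config, modulation=1e-12).frames[0]
        for o in range(3):
            s = raw.frames[3 * o : 3 * o + 3].sum(axis=0)
            assert np.allclose(s, 3.0 * uniform, rtol=1e-6, atol=1e-9)

    def test_seeded_bit_reproducibility(self, config):
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        a = render_sim_rawset(sc, config, noise=NoiseModel(30.0, seed=4))
        b = render_sim_rawset(sc, config, noise=NoiseModel(30.0, seed=4))
        assert np.array_equal(a.frames, b.frames)
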