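"""Structured-illumination band separation, pattern estimation, and
Wiener reconstruction."""

import numpy as np
import pytest

from maim.metrics import fwhm
from maim.optics import OpticalConfig
from maim.phantoms import (
    NoiseModel,
    Scene,
    SIMRawSet,
    make_microtubule_scene,
    make_point_scene,
    render_sim_rawset,
)
from maim.simrecon import (
    OTFModel,
    PatternNotFoundError,
    _phase_mixing_matrix,
    estimate_pattern,
    nominal_pattern_estimate,
    reconstruct,
    separate_bands,
)

EXTENT = 128 * 52.0


def bead_scene(seed: int, n: int = 400, extent: float = EXTENT) -> Scene:
    """Random flat bead field: broad-spectrum content for pattern
    estimation."""
    r = np.random.default_rng(seed)
    e = np.column_stack(
        [
            r.uniform(0.05 * extent, 0.95 * extent, n),
            r.uniform(0.05 * extent, 0.95 * extent, n),
            np.zeros(n),
            np.ones(n),
        ]
    )
    return Scene(e, (extent, extent))


class TestOTFModel:
    def test_basic_invariants(self, config):
        otf = OTFModel(cutoff=config.detection_cutoff)
        f = np.linspace(0, 2 * otf.cutoff, 500)
        vals = otf(f)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(vals[f >= otf.cutoff] == 0)
        assert np.all(np.diff(vals[f < otf.cutoff]) <= 1e-12)


class TestBandSeparation:
    def test_mixing_matrix_inverse_identity(self):
        phases = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        m = _phase_mixing_matrix(phases)
        assert np.allclose(m @ np.linalg.inv(m), np.eye(3), atol=1e-12)

    def test_duplicate_phases_rejected(self, config):
        sc = make_point_scene(extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config)
        bad = SIMRawSet(
            frames=raw.frames,
            pattern=type(raw.pattern)(
                orientations_deg=raw.pattern.orientations_deg,
                freq_cyc_per_nm=raw.pattern.freq_cyc_per_nm,
                phases=(0.0, 0.0, 0.0),
                modulation=raw.pattern.modulation,
            ),
            config=raw.config,
            tirf_theta_deg=raw.tirf_theta_deg,
        )
        with pytest.raises(ValueError, match="singular"):
            separate_bands(bad)

    def test_point_source_band_amplitude_ratio(self, config):
        # for a point emitter the side-band/center-band magnitude ratio is
        # exactly m/2 at every frequency
        sc = make_point_scene(z_nm=0.0, extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config, modulation=0.8)
        bands = separate_bands(raw)
        for o in range(3):
            r_plus = np.abs(bands[o, 1]).max() / np.abs(bands[o, 0]).max()
            r_minus = np.abs(bands[o, 2]).max() / np.abs(bands[o, 0]).max()
            assert r_plus == pytest.approx(0.4, rel=1e-9)
            assert r_minus == pytest.approx(0.4, rel=1e-9)

    def test_small_modulation_kills_side_bands(self, config):
        sc = bead_scene(0)
        raw = render_sim_rawset(sc, config, modulation=1e-9)
        bands = separate_bands(raw)
        side = np.abs(bands[:, 1:]).max()
        center = np.abs(bands[:, 0]).max()
        assert side < 1e-6 * center


class TestPatternEstimation:
    def test_recovers_frequency_phase_modulation(self, config):
        raw = render_sim_rawset(
            bead_scene(3), config, pattern_freq_fraction=0.9, modulation=0.8
        )
        est = estimate_pattern(raw)
        nom = nominal_pattern_estimate(raw)
        assert est.freqs == pytest.approx(nom.freqs, rel=0.005)
        for o in range(3):
            ang_est = np.degrees(np.arctan2(*est.k_vectors[o][::-1]))
            ang_nom = np.degrees(np.arctan2(*nom.k_vectors[o][::-1]))
            assert abs(ang_est - ang_nom) < 0.5
        assert np.all(est.modulations > 0.7)
        assert np.all(est.modulations < 0.9)

    def test_pure_noise_raises(self, config):
        rng = np.random.default_rng(0)
        sc = make_point_scene(extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config)
        noise_raw = SIMRawSet(
            frames=rng.normal(0, 1, raw.frames.shape),
            pattern=raw.pattern,
            config=raw.config,
            tirf_theta_deg=raw.tirf_theta_deg,
        )
        with pytest.raises(PatternNotFoundError):
            estimate_pattern(noise_raw)

    def test_k_vector_error_under_noise(self, config):
        # parameter recovery stays within 1% of truth across seeded noisy
        # replicates at SNR 30
        errs = []
        for seed in range(10):
            raw = render_sim_rawset(
                bead_scene(seed),
                config,
                pattern_freq_fraction=0.9,
                modulation=0.9,
                noise=NoiseModel(snr=30.0, seed=seed),
            )
            est = estimate_pattern(raw)
            nom = nominal_pattern_estimate(raw)
            errs.append(
                np.linalg.norm(est.k_vectors - nom.k_vectors, axis=1)
                / nom.freqs
            )
        assert np.max(errs) < 0.01


class TestWienerReconstruction:
    def test_point_fwhm_improvement(self, config):
        sc = make_point_scene(z_nm=0.0, extent_nm=256 * 52.0)
        raw = render_sim_rawset(
            sc, config, pattern_freq_fraction=0.9, modulation=0.9
        )
        sr = reconstruct(raw, pattern=nominal_pattern_estimate(raw))
        iy, _ = np.unravel_index(np.argmax(sr.image), sr.image.shape)
        w_sr = fwhm(sr.image[iy], np.arange(sr.image.shape[1]) * sr.pixel_nm)
        wf = raw.widefield()
        jy, _ = np.unravel_index(np.argmax(wf), wf.shape)
        w_wf = fwhm(wf[jy], np.arange(wf.shape[1]) * config.pixel_nm)
        assert w_sr <= 0.6 * w_wf

    def test_output_grid_is_twice_as_fine(self, config):
        sc = make_point_scene(extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config)
        sr = reconstruct(raw, pattern=nominal_pattern_estimate(raw))
        assert sr.image.shape == (2 * raw.frames.shape[1], 2 * raw.frames.shape[2])
        assert sr.pixel_nm == pytest.approx(config.pixel_nm / 2)

    def test_flat_field_invariance(self, config):
        g = np.arange(26.0, EXTENT, 52.0)
        xx, yy = np.meshgrid(g, g)
        plane = Scene(
            np.column_stack(
                [xx.ravel(), yy.ravel(), np.zeros(xx.size), np.ones(xx.size)]
            ),
            (EXTENT, EXTENT),
        )
        raw = render_sim_rawset(plane, config, modulation=0.9)
        sr = reconstruct(raw, pattern=nominal_pattern_estimate(raw))
        n = sr.image.shape[0]
        inner = sr.image[n // 4 : 3 * n // 4, n // 4 : 3 * n // 4]
        assert inner.std() / inner.mean() < 0.01

    def test_apodization_limits_spectral_support(self, config):
        sc = bead_scene(1)
        raw = render_sim_rawset(sc, config, modulation=0.9)
        pat = nominal_pattern_estimate(raw)
        sr = reconstruct(raw, pattern=pat)
        spec = np.abs(np.fft.fft2(sr.image)) ** 2
        fy = np.fft.fftfreq(sr.image.shape[0], sr.pixel_nm)
        fx = np.fft.fftfreq(sr.image.shape[1], sr.pixel_nm)
        fr = np.hypot(fy[:, None], fx[None, :])
        beyond = spec[fr > sr.effective_cutoff].sum()
        assert beyond < 1e-6 * spec.sum()

    def test_graceful_degradation_to_widefield(self, config):
        # with vanishing modulation the reconstruction converges to the
        # (upsampled, apodized) Wiener-deconvolved mean frame
        sc = make_microtubule_scene(4, extent_nm=EXTENT, seed=2)
        raw = render_sim_rawset(sc, config, modulation=0.05)
        pat = nominal_pattern_estimate(raw)
        sr = reconstruct(raw, pattern=pat)
        wf = raw.widefield()
        otf = OTFModel(cutoff=config.detection_cutoff)
        n = wf.shape[0]
        big = np.zeros((2 * n, 2 * n), dtype=complex)
        big_c = np.fft.fftshift(np.fft.fft2(wf))
        big[n // 2 : n // 2 + n, n // 2 : n // 2 + n] = big_c
        big = np.fft.ifftshift(big)
        fy = np.fft.fftfreq(2 * n, config.pixel_nm / 2)
        fr = np.hypot(fy[:, None], fy[None, :])
        h = otf(fr)
        apo = np.clip(1 - fr / sr.effective_cutoff, 0, 1)
        ref = np.real(np.fft.ifft2(big * 3 * h / (3 * h**2 + 0.1**2) * apo))
        corr = np.corrcoef(sr.image.ravel(), ref.ravel())[0, 1]
        assert corr > 0.999

    def test_invalid_wiener_parameter(self, config):
        sc = make_point_scene(extent_nm=EXTENT)
        raw = render_sim_rawset(sc, config)
        with pytest.raises(ValueError):
            reconstruct(
                raw, pattern=nominal_pattern_estimate(raw), wiener_w=0.0
            )
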