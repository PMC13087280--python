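"""QUS spectral estimator contracts and parameter recovery."""

import numpy as np
import pytest

from echogen import qus
from echogen.synthetic import bsc_model, simulate_rf_frame
from echogen.types import AcousticRegion, GridSpec, PhantomScene, RFFrame


def blank_frame(n_ax=512, n_ln=128, pitch=0.3125):
    return RFFrame(np.zeros((n_ax, n_ln)), 40.0, 1540.0, pitch)


def circular_core(frame, center_mm, radius_mm):
    ax = (np.arange(frame.n_axial) + 0.5) * frame.axial_pitch_mm
    lat = (np.arange(frame.n_lines) + 0.5) * frame.lateral_pitch_mm
    axg, latg = np.meshgrid(ax, lat, indexing="ij")
    return (axg - center_mm[0]) ** 2 + (latg - center_mm[1]) ** 2 \
        <= radius_mm ** 2


class TestROIMask:
    def test_zero_margin_is_core(self):
        frame = blank_frame()
        core = circular_core(frame, (5.0, 20.0), 2.0)
        roi = qus.make_roi_mask(core, frame, margin_mm=0.0)
        assert np.array_equal(roi.combined, core)

    def test_margin_band_width_matches_distance_transform(self):
        # 5 mm core + 2 mm margin -> outer boundary at 7 mm +/- one pixel
        frame = blank_frame(n_ax=1024, n_ln=128, pitch=0.3125)
        core = circular_core(frame, (10.0, 20.0), 5.0)
        roi = qus.make_roi_mask(core, frame, margin_mm=2.0)
        ax = (np.arange(frame.n_axial) + 0.5) * frame.axial_pitch_mm
        lat = (np.arange(frame.n_lines) + 0.5) * frame.lateral_pitch_mm
        axg, latg = np.meshgrid(ax, lat, indexing="ij")
        r = np.sqrt((axg - 10.0) ** 2 + (latg - 20.0) ** 2)
        outer = r[roi.combined].max()
        pix = max(frame.axial_pitch_mm, frame.lateral_pitch_mm)
        assert abs(outer - 7.0) <= pix + 1e-9

    def test_core_touching_edge_clips_without_error(self):
        frame = blank_frame()
        core = circular_core(frame, (1.0, 2.0), 1.5)
        roi = qus.make_roi_mask(core, frame, margin_mm=5.0)
        assert roi.combined.shape == frame.samples.shape

    def test_empty_core_rejected(self):
        frame = blank_frame()
        with pytest.raises(ValueError, match="empty"):
            qus.make_roi_mask(np.zeros_like(frame.samples, dtype=bool), frame)


class TestTileWindows:
    def test_94_percent_overlap_count(self):
        # 10 mm square ROI, 2 mm window, step 0.12 mm:
        # floor((10 - 2) / 0.12) + 1 = 67 positions per axis
        pitch = 0.125
        frame = blank_frame(n_ax=600, n_ln=96, pitch=pitch)
        n_ax_roi = int(round(10.0 / frame.axial_pitch_mm))
        n_ln_roi = int(round(10.0 / pitch))
        core = np.zeros_like(frame.samples, dtype=bool)
        core[10:10 + n_ax_roi, 8:8 + n_ln_roi] = True
        roi = qus.make_roi_mask(core, frame, margin_mm=0.0)
        windows = qus.tile_windows(roi, frame, window_mm=2.0, overlap=0.94)
        rows = {w.grid_row for w in windows}
        cols = {w.grid_col for w in windows}
        assert len(rows) == 67 and len(cols) == 67

    def test_zero_overlap_tiles_do_not_overlap(self):
        frame = blank_frame()
        core = np.ones_like(frame.samples, dtype=bool)
        roi = qus.make_roi_mask(core, frame, margin_mm=0.0)
        windows = qus.tile_windows(roi, frame, window_mm=2.0, overlap=0.0)
        starts = sorted({w.ax_start for w in windows})
        assert all(b - a >= windows[0].n_ax
                   for a, b in zip(starts, starts[1:]))

    def test_roi_smaller_than_window_is_empty(self):
        frame = blank_frame()
        core = np.zeros_like(frame.samples, dtype=bool)
        core[10:30, 3:5] = True  # < 1 x 1 mm
        roi = qus.make_roi_mask(core, frame, margin_mm=0.0)
        with pytest.warns(UserWarning):
            assert qus.tile_windows(roi, frame, window_mm=2.0) == []


class TestMeanPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(256) / 40.0  # us at 40 MHz
        win = np.tile(np.sin(2 * np.pi * 5.0 * t)[:, None], (1, 8))
        spec = qus.mean_power_spectrum(win, 40.0, fft_len=1024)
        assert spec.f_mhz[np.argmax(spec.power_db)] == pytest.approx(5.0,
                                                                     abs=0.1)

    def test_amplitude_doubling_adds_6dB(self):
        rng = np.random.default_rng(0)
        win = rng.normal(size=(128, 16))
        a = qus.mean_power_spectrum(win, 40.0)
        b = qus.mean_power_spectrum(2 * win, 40.0)
        assert np.allclose(b.power_db - a.power_db, 20 * np.log10(2),
                           atol=1e-9)

    def test_white_noise_is_flat_in_band(self):
        rng = np.random.default_rng(1)
        win = rng.normal(size=(256, 2000))
        spec = qus.mean_power_spectrum(win, 40.0)
        band = spec.power_db[(spec.f_mhz > 2) & (spec.f_mhz < 18)]
        assert band.max() - band.min() < 1.5

    def test_all_zero_window_flagged(self):
        spec = qus.mean_power_spectrum(np.zeros((64, 4)), 40.0)
        assert spec.flagged

    def test_single_line_rejected(self):
        with pytest.raises(ValueError):
            qus.mean_power_spectrum(np.zeros((64, 1)), 40.0)


class TestNormalizeSpectrum:
    def test_self_normalization_is_zero(self):
        f = np.linspace(0, 20, 100)
        s = qus.MeanPowerSpectrum(f, np.random.default_rng(0).normal(size=100),
                                  4)
        assert np.allclose(qus.normalize_spectrum(s, s), 0.0)

    def test_offset_passes_through(self):
        f = np.linspace(0, 20, 50)
        a = qus.MeanPowerSpectrum(f, np.zeros(50), 4)
        b = qus.MeanPowerSpectrum(f, np.full(50, 3.0), 4)
        assert np.allclose(qus.normalize_spectrum(b, a), 3.0)

    def test_grid_mismatch_rejected(self):
        a = qus.MeanPowerSpectrum(np.linspace(0, 20, 50), np.zeros(50), 4)
        b = qus.MeanPowerSpectrum(np.linspace(0, 10, 50), np.zeros(50), 4)
        with pytest.raises(ValueError):
            qus.normalize_spectrum(a, b)


class TestAttenuation:
    def test_identical_media_recover_reference_alpha(self):
        f = np.linspace(4, 13, 40)
        depths = np.linspace(1.0, 2.5, 6)
        spectra = np.tile(5.0 - 0.3 * f, (6, 1))  # no depth decay
        est = qus.estimate_ace(depths, spectra, f, (4, 13), alpha_ref=0.786)
        assert est.ace_db_mhz_cm == pytest.approx(0.786, abs=1e-9)

    def test_known_exponential_decay_recovered(self):
        f = np.linspace(4, 13, 40)
        depths = np.linspace(1.0, 3.0, 9)
        alpha = 1.5
        spectra = np.array([-2 * (alpha - 0.786) * f * z + 4.0 - 0.2 * f
                            for z in depths])
        est = qus.estimate_ace(depths, spectra, f, (4, 13), alpha_ref=0.786)
        assert est.ace_db_mhz_cm == pytest.approx(1.5, abs=0.1)

    def test_too_few_depths_rejected(self):
        f = np.linspace(4, 13, 10)
        with pytest.raises(ValueError, match="3 depths"):
            qus.estimate_ace([1.0, 2.0], np.zeros((2, 10)), f, (4, 13), 0.786)

    def test_zero_alpha_correction_is_identity(self):
        f = np.linspace(3, 13, 30)
        s = np.random.default_rng(2).normal(size=30)
        assert np.allclose(qus.correct_attenuation(s, [(0.0, 1.0)], f), s)

    def test_point_compensation_closed_form(self):
        # alpha = 1 dB/MHz/cm, 1 cm path, 5 MHz -> +10 dB (round trip)
        out = qus.correct_attenuation(np.zeros(1), [(1.0, 1.0)],
                                      np.array([5.0]))
        assert out[0] == pytest.approx(10.0)

    def test_forward_then_compensation_round_trip(self):
        f = np.linspace(3, 13, 60)
        layers = [(1.0, 0.8), (1.7, 1.2)]
        decayed = -sum(2 * a * f * p for a, p in layers)
        restored = qus.correct_attenuation(decayed, layers, f)
        assert np.abs(restored).max() <= 0.1

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            qus.correct_attenuation(np.zeros(3), [(1.0, -0.5)],
                                    np.array([1.0, 2.0, 3.0]))


class TestSpectralFit:
    def test_flat_spectrum(self):
        f = np.linspace(3, 8, 30)
        fit = qus.fit_spectral_params(np.zeros(30), f, (3, 8))
        assert (fit.ss_db_mhz, fit.si_db, fit.mbf_db) == (0.0, 0.0, 0.0)

    def test_exact_on_linear_spectrum(self):
        f = np.linspace(3, 8, 50)
        fit = qus.fit_spectral_params(2.0 * f - 5.0, f, (3, 8))
        assert fit.ss_db_mhz == pytest.approx(2.0, abs=1e-9)
        assert fit.si_db == pytest.approx(-5.0, abs=1e-9)
        assert fit.mbf_db == pytest.approx(2.0 * 5.5 - 5.0, abs=1e-9)

    def test_gain_shifts_mbf_si_not_ss(self):
        f = np.linspace(3, 8, 50)
        a = qus.fit_spectral_params(2.0 * f - 5.0, f, (3, 8))
        b = qus.fit_spectral_params(2.0 * f - 2.0, f, (3, 8))
        assert b.ss_db_mhz == pytest.approx(a.ss_db_mhz, abs=1e-9)
        assert b.si_db - a.si_db == pytest.approx(3.0, abs=1e-9)
        assert b.mbf_db - a.mbf_db == pytest.approx(3.0, abs=1e-9)

    def test_mbf_identity(self):
        rng = np.random.default_rng(3)
        f = np.linspace(4, 12, 40)
        for _ in range(10):
            fit = qus.fit_spectral_params(rng.normal(size=40), f, (4, 12))
            fc = 0.5 * (fit.band[0] + fit.band[1])
            assert fit.mbf_db == pytest.approx(
                fit.ss_db_mhz * fc + fit.si_db, abs=1e-9)


class TestFormFactorFit:
    CAL = {"a_eff_um": 12.5, "density_per_mm2": 100.0,
           "speed_of_sound_mps": 1540.0, "kappa": 1.0,
           "amplitude_variance": 1.0}

    def test_bsc_identity_when_corrected_is_zero(self):
        f = np.linspace(4, 13, 50)
        curve = qus.estimate_bsc(np.zeros(50), f, self.CAL)
        assert np.allclose(curve.bsc, bsc_model(f, 12.5, 100.0))

    def test_plus_10_db_is_times_10(self):
        f = np.linspace(4, 13, 50)
        a = qus.estimate_bsc(np.zeros(50), f, self.CAL)
        b = qus.estimate_bsc(np.full(50, 10.0), f, self.CAL)
        assert np.allclose(b.bsc, 10.0 * a.bsc)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            qus.estimate_bsc(np.zeros(5), np.linspace(4, 13, 5), {})

    def test_noiseless_model_recovered_exactly(self):
        f = np.linspace(4, 13, 50)
        curve = qus.BackscatterCurve(f, bsc_model(f, 50.0, 30.0))
        fit = qus.fit_gaussian_form_factor(curve, (4, 13))
        assert fit.esd_um == pytest.approx(100.0, rel=1e-9)
        assert fit.eac_db == pytest.approx(10 * np.log10(30.0), abs=1e-9)

    def test_scaling_moves_eac_not_esd(self):
        f = np.linspace(4, 13, 50)
        base = qus.fit_gaussian_form_factor(
            qus.BackscatterCurve(f, bsc_model(f, 50.0, 30.0)), (4, 13))
        scaled = qus.fit_gaussian_form_factor(
            qus.BackscatterCurve(f, 7.0 * bsc_model(f, 50.0, 30.0)), (4, 13))
        assert scaled.esd_um == pytest.approx(base.esd_um, rel=1e-12)
        assert scaled.eac_db - base.eac_db == pytest.approx(
            10 * np.log10(7.0), abs=1e-9)

    def test_esd_under_multiplicative_noise(self):
        """5% multiplicative BSC noise, 50 bins: median error < 10%
        over 100 trials."""
        rng = np.random.default_rng(42)
        f = np.linspace(4, 13, 50)
        clean = bsc_model(f, 75.0, 10.0)
        errs = []
        for _ in range(100):
            noisy = clean * (1 + 0.05 * rng.normal(size=50))
            fit = qus.fit_gaussian_form_factor(
                qus.BackscatterCurve(f, np.abs(noisy)), (4, 13))
            errs.append(abs(fit.esd_um - 150.0) / 150.0)
        assert np.median(errs) < 0.10

    def test_degenerate_positive_slope_flagged(self):
        f = np.linspace(4, 13, 50)
        k = 2 * np.pi * f * 1e6 / 1540.0
        rising = k ** 4 * np.exp(+1e-10 * k ** 2)
        fit = qus.fit_gaussian_form_factor(qus.BackscatterCurve(f, rising),
                                           (4, 13))
        assert fit.degenerate and fit.a_eff_um == 0.0


class TestParametricMaps:
    def test_self_normalization_gives_zero_maps(self, pulse, wide_grid,
                                                reference_frame):
        from echogen.synthetic import simulate_reference_frame
        sample = simulate_reference_frame(pulse, wide_grid, seed=21)
        core = np.zeros(sample.samples.shape, dtype=bool)
        core[150:360, 30:220] = True
        roi = qus.make_roi_mask(core, sample, margin_mm=0.0)
        cfg = qus.QUSConfig(overlap=0.5, estimate_tumor_ace=False,
                            intervening_alpha=0.786,
                            tumor_alpha_prior=0.786)
        maps = qus.build_parametric_maps(sample, reference_frame, roi, cfg)
        assert abs(np.median(maps.maps["MBF"][maps.valid])) < 1.0
        assert abs(np.median(maps.maps["SS"][maps.valid])) < 0.5

    def test_esd_recovery_on_homogeneous_frame(self, homogeneous_frame,
                                               reference_frame):
        core = np.zeros(homogeneous_frame.samples.shape, dtype=bool)
        core[100:412, 20:236] = True
        roi = qus.make_roi_mask(core, homogeneous_frame, margin_mm=0.0)
        cfg = qus.QUSConfig(overlap=0.5, estimate_tumor_ace=False)
        maps = qus.build_parametric_maps(homogeneous_frame, reference_frame,
                                         roi, cfg)
        esd = maps.maps["ESD"][maps.valid]
        assert abs(np.median(esd) - 150.0) / 150.0 < 0.10

    def test_esd_map_contrast_sign_on_two_region_scene(self, pulse, wide_grid,
                                                       reference_frame):
        bg = AcousticRegion(a_eff_um=100.0, density_per_mm2=8.0,
                            attenuation_db_mhz_cm=1.0)
        lesion = AcousticRegion(a_eff_um=50.0, density_per_mm2=16.0,
                                attenuation_db_mhz_cm=1.0,
                                geometry=(4.9, 40.0, 2.2, 6.0))
        rf = simulate_rf_frame(PhantomScene(regions=(bg, lesion), seed=13),
                               pulse, wide_grid)
        from echogen.synthetic import _roi_mask_from_ellipse
        core = _roi_mask_from_ellipse((4.9, 40.0, 2.2, 6.0), wide_grid, pulse)
        roi = qus.make_roi_mask(core, rf, margin_mm=5.0)
        cfg = qus.QUSConfig(overlap=0.7, estimate_tumor_ace=False)
        maps = qus.build_parametric_maps(rf, reference_frame, roi, cfg)
        esd_core = np.median(maps.maps["ESD"][maps.valid & (maps.region == 2)])
        esd_marg = np.median(maps.maps["ESD"][maps.valid & (maps.region == 1)])
        assert esd_core < esd_marg  # smaller scatterers inside the lesion

    def test_amplitude_scaling_property(self, homogeneous_frame,
                                        reference_frame):
        """RF x s: MBF, SI, EAC shift by 20 log10 s; SS, ESD unchanged."""
        s = 3.0
        scaled = RFFrame(homogeneous_frame.samples * s, 40.0, 1540.0,
                         homogeneous_frame.lateral_pitch_mm)
        core = np.zeros(homogeneous_frame.samples.shape, dtype=bool)
        core[150:360, 30:220] = True
        roi = qus.make_roi_mask(core, homogeneous_frame, margin_mm=0.0)
        cfg = qus.QUSConfig(overlap=0.5, estimate_tumor_ace=False)
        a = qus.build_parametric_maps(homogeneous_frame, reference_frame, roi,
                                      cfg)
        b = qus.build_parametric_maps(scaled, reference_frame, roi, cfg)
        shift = 20 * np.log10(s)
        v = a.valid & b.valid
        for name in ("MBF", "SI", "EAC"):
            assert np.allclose(b.maps[name][v] - a.maps[name][v], shift,
                               atol=1e-6)
        for name in ("SS", "ESD"):
            assert np.allclose(b.maps[name][v], a.maps[name][v], atol=1e-6)

    def test_map_grid_matches_window_count(self, homogeneous_frame,
                                           reference_frame):
        core = np.zeros(homogeneous_frame.samples.shape, dtype=bool)
        core[150:360, 30:220] = True
        roi = qus.make_roi_mask(core, homogeneous_frame, margin_mm=0.0)
        windows = qus.tile_windows(roi, homogeneous_frame, 2.0, 0.5)
        cfg = qus.QUSConfig(overlap=0.5, estimate_tumor_ace=False)
        maps = qus.build_parametric_maps(homogeneous_frame, reference_frame,
                                         roi, cfg)
        assert (maps.region > 0).sum() == len(windows)

    def test_mean_value_features(self):
        maps = qus.ParametricMapSet(
            maps={n: np.array([[1.0, 3.0]]) for n in qus.MAP_NAMES},
            valid=np.array([[True, True]]),
            region=np.array([[2, 1]], dtype=np.int8),
            center_depth_cm=np.zeros((1, 2)),
            center_lateral_mm=np.zeros((1, 2)),
            window_mm=2.0, overlap=0.94, band=(4.0, 13.0))
        assert qus.mean_value_features(maps, "core")["MBF"] == 1.0
        assert qus.mean_value_features(maps, "both")["MBF"] == 2.0
        maps.valid[0, 1] = False
        assert qus.mean_value_features(maps, "both")["MBF"] == 1.0
        with pytest.raises(ValueError):
            qus.mean_value_features(maps, "margin")
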