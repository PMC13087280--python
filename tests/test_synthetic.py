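"""Simulator contracts: scatterer statistics, delay geometry, spectra."""

import numpy as np
import pytest
from scipy.signal import hilbert

from echogen.synthetic import (DatasetConfig, bsc_model, build_paired_dataset,
                               form_bmode, sample_scatterer_field,
                               simulate_reference_frame, simulate_rf_frame)
from echogen.qus import _batch_mean_spectra
from echogen.types import AcousticRegion, GridSpec, PhantomScene, PulseModel


def scene_with(density, a_eff=50.0, seed=0, **kw):
    return PhantomScene(regions=(AcousticRegion(
        a_eff_um=a_eff, density_per_mm2=density, **kw),), seed=seed)


class TestScattererField:
    def test_zero_density_yields_no_scatterers(self, pulse, desk_grid):
        pos, amp, rid = sample_scatterer_field(scene_with(0.0), desk_grid,
                                               pulse)
        assert len(amp) == 0

    def test_poisson_count_matches_density_times_area(self, pulse):
        # 40 mm depth x 60 mm width at n = 12 / mm^2 -> mean 28800
        fs, c = pulse.sampling_rate_mhz, pulse.speed_of_sound_mps
        n_axial = int(round(40.0 / (c / (2 * fs * 1e6) * 1e3)))
        grid = GridSpec(n_axial=n_axial, n_lines=120, lateral_pitch_mm=0.5)
        assert abs(grid.depth_mm(pulse) - 40.0) < 0.02
        pos, amp, _ = sample_scatterer_field(scene_with(12.0, seed=5), grid,
                                             pulse)
        mean = 12.0 * grid.depth_mm(pulse) * grid.width_mm()
        assert abs(len(amp) - mean) < 4 * np.sqrt(mean)

    def test_same_seed_gives_identical_field(self, pulse, desk_grid):
        a = sample_scatterer_field(scene_with(5.0, seed=9), desk_grid, pulse)
        b = sample_scatterer_field(scene_with(5.0, seed=9), desk_grid, pulse)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_lesion_outside_grid_errors(self, pulse, desk_grid):
        bg = AcousticRegion(a_eff_um=50, density_per_mm2=5)
        lesion = AcousticRegion(a_eff_um=50, density_per_mm2=5,
                                geometry=(5.0, 100.0, 2.0, 2.0))
        scene = PhantomScene(regions=(bg, lesion), seed=0)
        with pytest.raises(ValueError, match="outside"):
            sample_scatterer_field(scene, desk_grid, pulse)

    def test_amplitude_variance_scales_with_region(self, pulse, desk_grid):
        _, amp, _ = sample_scatterer_field(
            scene_with(50.0, amplitude_variance=4.0, seed=2), desk_grid, pulse)
        assert amp.var() == pytest.approx(4.0, rel=0.2)


class TestRFSynthesis:
    def test_zero_scatterers_gives_zero_frame(self, pulse, desk_grid):
        rf = simulate_rf_frame(scene_with(0.0), pulse, desk_grid)
        assert np.all(rf.samples == 0.0)

    def test_point_target_delay(self, pulse):
        # round(2 * 20 mm * fs / c) = 1039 for fs = 40 MHz, c = 1540 m/s
        grid = GridSpec(n_axial=2080, n_lines=8, lateral_pitch_mm=0.3125)
        scat = (np.array([[20.0, 1.0]]), np.array([1.0]), np.array([0]))
        rf = simulate_rf_frame(scene_with(0.0), pulse, grid, scatterers=scat)
        line = int(1.0 / grid.lateral_pitch_mm)
        env = np.abs(hilbert(rf.samples[:, line]))
        expected = round(2 * 20e-3 / 1540.0 * 40e6)
        assert expected == 1039
        assert abs(int(env.argmax()) - expected) <= 1

    def test_round_trip_spectral_contract(self, pulse, wide_grid,
                                          reference_frame):
        """Window-averaged spectrum ratio matches the generating BSC model
        within 1 dB RMS when sample and reference share attenuation."""
        bg = AcousticRegion(a_eff_um=60.0, density_per_mm2=12.0,
                            attenuation_db_mhz_cm=0.786)
        rf = simulate_rf_frame(PhantomScene(regions=(bg,), seed=5), pulse,
                               wide_grid)
        blocks = [(a, l) for a in range(100, 400, 52)
                  for l in range(0, 250, 7)]
        arr_s = np.stack([rf.samples[a:a + 104, l:l + 6] for a, l in blocks])
        arr_r = np.stack([reference_frame.samples[a:a + 104, l:l + 6]
                          for a, l in blocks])
        f, sdb = _batch_mean_spectra(arr_s, 40.0, 1024)
        _, rdb = _batch_mean_spectra(arr_r, 40.0, 1024)
        norm = (sdb - rdb).mean(axis=0)
        sel = (f >= 7.7) & (f <= 13.3)
        model = 10 * np.log10(bsc_model(f[sel], 60.0, 12.0)
                              / bsc_model(f[sel], 12.5, 100.0))
        assert np.sqrt(np.mean((norm[sel] - model) ** 2)) < 1.0

    def test_reference_frame_metadata(self, reference_frame):
        assert reference_frame.calibration["alpha_db_mhz_cm"] == 0.786
        assert reference_frame.calibration["speed_of_sound_mps"] == 1540.0
        assert reference_frame.provenance == "reference"

    def test_reference_seeds_share_expected_spectrum(self, pulse):
        grid = GridSpec(n_axial=512, n_lines=128)
        a = simulate_reference_frame(pulse, grid, seed=1)
        b = simulate_reference_frame(pulse, grid, seed=2)
        assert not np.allclose(a.samples, b.samples)
        blocks = [(x, l) for x in range(50, 400, 52) for l in range(0, 120, 6)]
        f, da = _batch_mean_spectra(
            np.stack([a.samples[x:x + 104, l:l + 6] for x, l in blocks]),
            40.0, 1024)
        _, db = _batch_mean_spectra(
            np.stack([b.samples[x:x + 104, l:l + 6] for x, l in blocks]),
            40.0, 1024)
        sel = (f > 7.7) & (f < 13.3)
        diff = da.mean(axis=0)[sel] - db.mean(axis=0)[sel]
        assert np.abs(diff).max() < 1.5  # Monte-Carlo tolerance


class TestBMode:
    def test_all_zero_rf_maps_to_zero_image(self, pulse, desk_grid):
        rf = simulate_rf_frame(scene_with(0.0), pulse, desk_grid)
        img = form_bmode(rf)
        assert np.all(img.pixels == 0.0)

    def test_single_echo_is_bright_blob_at_depth(self, pulse):
        grid = GridSpec(n_axial=2080, n_lines=8, lateral_pitch_mm=0.3125)
        scat = (np.array([[20.0, 1.0]]), np.array([1.0]), np.array([0]))
        rf = simulate_rf_frame(scene_with(0.0), pulse, grid, scatterers=scat)
        img = form_bmode(rf, dynamic_range_db=60.0)
        r, c = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert abs(r - 1039) <= 1
        assert img.pixels[r, c] == pytest.approx(1.0)
        # brightness decays monotonically with larger dynamic range off-peak
        img40 = form_bmode(rf, dynamic_range_db=40.0)
        off = img.pixels[r + 200, c], img40.pixels[r + 200, c]
        assert off[1] <= off[0]

    def test_resampling_to_display_shape(self, pulse, desk_grid):
        rf = simulate_rf_frame(scene_with(10.0, seed=1), pulse, desk_grid)
        img = form_bmode(rf, out_shape=(373, 541))
        assert img.pixels.shape == (373, 541)
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0


class TestPairedDataset:
    def test_pair_count(self, tiny_dataset):
        # 2 lesions/class x 2 classes x 4 planes
        assert len(tiny_dataset.samples) == 16

    def test_determinism(self):
        cfg = DatasetConfig(n_lesions_per_class=1, n_planes=2)
        a = build_paired_dataset(cfg, seed=4)
        b = build_paired_dataset(cfg, seed=4)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.rf.samples, sb.rf.samples)
            assert np.array_equal(sa.bmode.pixels, sb.bmode.pixels)

    def test_ground_truth_recorded(self, tiny_dataset):
        for s in tiny_dataset.samples:
            lesion = s.scene.regions[1]
            lo, hi = (80.0, 110.0) if s.class_label == "benign" else (20.0, 105.0)
            assert lo <= lesion.a_eff_um <= hi
            assert s.roi_mask.any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(n_lesions_per_class=0)
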