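"""Synthetic bruising-experiment generator: physics, bookkeeping, spectra."""

import numpy as np
import pytest

import brulat as bl
from brulat.simulate import (BALL_MASS_KG, LEVEL_CODES, demo_config,
                             full_manifest, level_by_code,
                             replica_manifest, simulate_to_dir)


class TestImpactEnergy:
    @pytest.mark.parametrize("height,expected", [
        (0.020, 0.013), (0.040, 0.025), (0.07, 0.044),
        (0.126, 0.079), (0.219, 0.137), (0.319, 0.200),
    ])
    def test_energy_matches_study_levels(self, height, expected):
        assert bl.energy_from_drop(BALL_MASS_KG, height) == pytest.approx(expected)

    def test_zero_height_gives_zero_energy(self):
        assert bl.energy_from_drop(BALL_MASS_KG, 0.0) == 0.0

    @pytest.mark.parametrize("mass,height", [(-1, 0.1), (0, 0.1), (0.1, -0.5)])
    def test_invalid_arguments_raise(self, mass, height):
        with pytest.raises(ValueError):
            bl.energy_from_drop(mass, height)


class TestSeverityTable:
    def test_per_level_totals_and_grand_total(self):
        totals = [lv.total_samples for lv in bl.severity_table()]
        assert totals == [36, 36, 36, 30, 24, 24]
        assert bl.grand_total() == 186

    def test_energy_strictly_increases_with_height(self):
        energies = [lv.impact_energy_J for lv in bl.severity_table()]
        assert all(a < b for a, b in zip(energies, energies[1:]))

    def test_zero_scan_times_gives_zero_samples(self):
        lv = bl.BruiseLevel("L9", 0.1, 0.05, 0, 0)
        assert lv.total_samples == 0


class TestSoundSpectrum:
    def test_range_and_determinism(self, default_config):
        grid = default_config.grid
        s1 = bl.sound_spectrum(grid, seed=3)
        s2 = bl.sound_spectrum(grid, seed=3)
        assert np.array_equal(s1, s2)
        assert np.all((s1 > 0) & (s1 <= 1))

    def test_water_band_dip_at_1450(self, default_config):
        grid = default_config.grid
        s = bl.sound_spectrum(grid, seed=3)
        wl = np.asarray(grid)
        assert s[np.argmin(np.abs(wl - 1450))] < s[np.argmin(np.abs(wl - 1250))]

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            bl.sound_spectrum(np.array([]), seed=0)


class TestBruiseSpectrum:
    def _gap(self, energy, hours, grid, sound):
        wl = np.asarray(grid)
        band = (wl >= 952) & (wl <= 1377)
        bruised = bl.bruise_spectrum(sound, energy, hours, grid)
        return np.trapezoid(np.abs(sound - bruised)[band], wl[band])

    def test_zero_energy_is_identity(self, default_config):
        grid = default_config.grid
        sound = bl.sound_spectrum(grid, seed=1)
        assert np.array_equal(bl.bruise_spectrum(sound, 0.0, 6, grid), sound)

    def test_reflectance_never_exceeds_sound(self, default_config):
        grid = default_config.grid
        sound = bl.sound_spectrum(grid, seed=1)
        bruised = bl.bruise_spectrum(sound, 0.2, 72, grid)
        assert np.all(bruised <= sound + 1e-12)

    def test_gap_increases_with_energy(self, default_config):
        grid = default_config.grid
        sound = bl.sound_spectrum(grid, seed=1)
        gaps = [self._gap(lv.impact_energy_J, 6, grid, sound)
                for lv in bl.severity_table()]
        assert all(a < b for a, b in zip(gaps, gaps[1:]))

    def test_gap_monotone_in_time(self, default_config):
        grid = default_config.grid
        sound = bl.sound_spectrum(grid, seed=1)
        gaps = [self._gap(0.013, h, grid, sound) for h in (1, 6, 18, 48, 72)]
        assert all(a <= b for a, b in zip(gaps, gaps[1:]))

    def test_negative_energy_raises(self, default_config):
        grid = default_config.grid
        sound = bl.sound_spectrum(grid, seed=1)
        with pytest.raises(ValueError):
            bl.bruise_spectrum(sound, -0.1, 6, grid)


class TestGenerateHypercube:
    def test_shape_and_masks(self, l2_cube, default_config):
        cube, truth = l2_cube
        assert cube.shape == (default_config.lines, default_config.samples,
                              default_config.band_count)
        assert truth.bruise_mask.any()
        assert not np.any(truth.bruise_mask & ~truth.fruit_mask)

    def test_sound_level_has_empty_bruise_mask(self, sound_cube):
        _, truth = sound_cube
        assert not truth.bruise_mask.any()

    def test_determinism(self, default_config):
        c1, t1 = bl.generate_hypercube(default_config, "L3", 18, seed=9)
        c2, t2 = bl.generate_hypercube(default_config, "L3", 18, seed=9)
        assert np.array_equal(c1.data, c2.data)
        assert np.array_equal(t1.bruise_mask, t2.bruise_mask)

    def test_painted_gap_matches_bruise_spectrum(self):
        # isolate the painted signal: no fruit-level nuisance components
        cfg = bl.SimulationConfig(tissue_heterogeneity_sd=0.0,
                                  fruit_variability_sd=0.0, fruit_scale_sd=0.0,
                                  amplitude_jitter_sd=0.0,
                                  deterioration_jitter_sd=0.0)
        cube, truth = bl.generate_hypercube(cfg, "L4", 18, seed=3)
        bruise_mean = bl.roi_mean_spectrum(cube, truth.bruise_mask)
        fruit_mean = bl.roi_mean_spectrum(
            cube, truth.fruit_mask & ~truth.bruise_mask)
        grid = cfg.grid
        sound = bl.sound_spectrum(grid, seed=np.random.default_rng(3)
                                  .integers(2 ** 31), variability_sd=0.0,
                                  scale_sd=0.0)
        expected_gap = sound - bl.bruise_spectrum(
            sound, level_by_code("L4").impact_energy_J, 18, grid)
        observed_gap = fruit_mean - bruise_mean
        tol = 5 * cfg.noise_sd / np.sqrt(truth.bruise_mask.sum())
        assert np.max(np.abs(observed_gap - expected_gap)) < tol

    def test_contrast_strictly_increases_with_level(self, default_config):
        contrasts = []
        for level in LEVEL_CODES:
            cube, truth = bl.generate_hypercube(default_config, level, 6, seed=4)
            gap = (bl.roi_mean_spectrum(cube, truth.fruit_mask & ~truth.bruise_mask)
                   - bl.roi_mean_spectrum(cube, truth.bruise_mask))
            contrasts.append(np.linalg.norm(gap))
        assert all(a < b for a, b in zip(contrasts, contrasts[1:]))

    def test_background_is_dark(self, l2_cube, default_config):
        cube, truth = l2_cube
        bg = cube.data[~truth.fruit_mask].mean()
        assert bg < 0.1

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            bl.SimulationConfig(lines=32, samples=32, fruit_axes=(28, 26))
        with pytest.raises(ValueError):
            bl.SimulationConfig(bruise_radius_px=40)

    def test_unknown_level_raises(self, default_config):
        with pytest.raises(ValueError):
            bl.generate_hypercube(default_config, "L7", 1, seed=0)


class TestManifests:
    def test_replica_manifest_replays_bookkeeping(self):
        m = replica_manifest(0)
        assert len(m) == 186
        per_level = m.groupby("level").size()
        assert per_level.tolist() == [36, 36, 36, 30, 24, 24]

    def test_full_manifest_covers_grid(self):
        m = full_manifest(0, n_per_batch=1)
        assert len(m) == 6 * 5 * 2
        assert set(zip(m.level, m.hours)) == {
            (lv, h) for lv in LEVEL_CODES for h in (1, 6, 18, 48, 72)}

    def test_manifest_seeds_unique_and_bounded(self):
        m = replica_manifest(3)
        assert m.seed.is_unique
        assert (m.seed < 2 ** 31).all() and (m.seed >= 0).all()


def test_simulate_to_dir_roundtrip(tmp_path):
    cfg = bl.SimulationConfig()
    manifest = full_manifest(0, levels=("L2",), hours=(1,), n_per_batch=1,
                             batches=(1,))
    written = simulate_to_dir(cfg, manifest, tmp_path)
    assert (tmp_path / "manifest.csv").exists()
    cube = bl.read_envi(written.cube_path.iloc[0])
    ref, _ = bl.generate_hypercube(cfg, "L2", 1, int(written.seed.iloc[0]))
    assert np.allclose(cube.data, ref.data.astype(np.float32))


def test_demo_config_geometry_valid():
    cfg = demo_config()
    assert cfg.lines == 96 and cfg.bruise_radius_px < min(cfg.fruit_axes)
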