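"""Synthetic tissue generator: geometry, layer means, decay rendering."""

import numpy as np
import pytest

import epiflim as ef
from epiflim.config import InvalidConfigError
from epiflim.synthetic import N_LAYERS


def _flat_config(**kw):
    defaults = dict(
        image_size=256,
        boundary_waviness_amplitude=0.0,
        epithelium_thickness_mean=144.0,
        epithelium_thickness_sd=0.0,
    )
    defaults.update(kw)
    return ef.SyntheticConfig(**defaults)


class TestMakeGeometry:
    def test_flat_band_is_two_horizontal_lines_80px_apart(self):
        cfg = _flat_config()  # 144 um at 1.8 um/px = 80 px
        geo = ef.make_geometry(cfg, np.random.default_rng(0))
        sep = geo.membrane[:, 1] - geo.surface[:, 1]
        assert np.allclose(sep, 80.0)
        assert np.ptp(geo.membrane[:, 1]) == 0.0
        assert np.ptp(geo.surface[:, 1]) == 0.0

    def test_deterministic_under_seed(self):
        cfg = ef.SyntheticConfig()
        a = ef.make_geometry(cfg, np.random.default_rng(7))
        b = ef.make_geometry(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.membrane, b.membrane)
        np.testing.assert_array_equal(a.surface, b.surface)

    def test_sinusoidal_waviness_modulates_separation(self):
        cfg = _flat_config(
            boundary_waviness_amplitude=20.0, boundary_waviness_period=230.0
        )
        geo = ef.make_geometry(cfg, np.random.default_rng(3))
        sep_um = (geo.membrane[:, 1] - geo.surface[:, 1]) * cfg.pixel_size
        # image spans ~2 periods, so min/max reach thickness -/+ amplitude
        assert sep_um.min() == pytest.approx(144.0 - 20.0, abs=0.5)
        assert sep_um.max() == pytest.approx(144.0 + 20.0, abs=0.5)

    def test_band_larger_than_image_rejected(self):
        cfg = ef.SyntheticConfig(image_size=64, epithelium_thickness_mean=300.0)
        with pytest.raises(InvalidConfigError):
            cfg.validate()


class TestSampleLayerMeans:
    def test_zero_rsd_returns_profile_exactly(self):
        cfg = ef.SyntheticConfig(sample_rsd=0.0)
        for label in ef.PATHOLOGY_CLASSES:
            means = ef.sample_layer_means(label, cfg, np.random.default_rng(0))
            np.testing.assert_array_equal(means, cfg.class_profile[label])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ef.sample_layer_means("CIN4", ef.SyntheticConfig(), np.random.default_rng(0))

    def test_layer10_contrast_matches_245ps(self):
        prof = ef.default_class_profile()
        assert prof["normal"][9] - prof["CIN3"][9] == pytest.approx(245.0, abs=1.0)
        assert prof["normal"][5] - prof["CIN3"][5] == pytest.approx(147.0, abs=1.0)

    def test_normal_rises_and_cin3_flat_in_top_half(self):
        prof = ef.default_class_profile()
        assert np.all(np.diff(prof["normal"]) > 0)
        top = prof["CIN3"][5:]
        assert np.ptp(top) < 40.0  # maturation arrest: near-flat

    def test_empirical_rsd_matches_configured_value(self):
        cfg = ef.SyntheticConfig(sample_rsd=0.15)
        rng = np.random.default_rng(11)
        draws = np.array(
            [ef.sample_layer_means("normal", cfg, rng) for _ in range(10_000)]
        )
        rsd = draws.std(axis=0) / draws.mean(axis=0)
        assert np.all(np.abs(rsd - 0.15) < 0.01)

    def test_structured_noise_rsd_within_observed_band(self):
        cfg = ef.SyntheticConfig()
        rng = np.random.default_rng(5)
        draws = np.array(
            [ef.sample_layer_means("CIN1", cfg, rng) for _ in range(5_000)]
        )
        rsd = draws.std(axis=0) / draws.mean(axis=0)
        # basal layers ~0.23, superficial ~0.15; layer average ~0.19
        assert np.all(rsd > 0.13) and np.all(rsd < 0.26)
        assert 0.15 <= rsd.mean() <= 0.20


class TestRenderDecayCube:
    def test_single_exponential_limit(self, noiseless_config):
        cfg = noiseless_config
        cfg.amp_ratio = 0.0  # no instrumental component
        cfg.irf_sigma = 0.0
        cfg.irf_center = 0.0
        cfg.background_photons = 0.0
        rng = np.random.default_rng(0)
        sample = ef.generate_sample("normal", cfg, rng, render=False)
        expected = ef.render_decay_cube(sample.true_tau2_map, cfg, rng, poisson=False)
        yy, xx = np.nonzero(sample.roi_mask)
        y0, x0 = yy[0], xx[0]
        tau2 = sample.true_tau2_map[y0, x0]
        t = (np.arange(cfg.n_time_bins) + 0.5) * cfg.bin_width
        model = np.exp(-t / tau2)
        curve = expected[y0, x0]
        np.testing.assert_allclose(
            curve / curve[0], model / model[0], rtol=1e-10
        )

    def test_expected_counts_normalized_to_photon_budget(self, noiseless_config):
        rng = np.random.default_rng(1)
        sample = ef.generate_sample("CIN2", noiseless_config, rng, render=False)
        expected = ef.render_decay_cube(
            sample.true_tau2_map, noiseless_config, rng, poisson=False
        )
        totals = expected[sample.roi_mask].sum(axis=1)
        np.testing.assert_allclose(
            totals, noiseless_config.photons_per_pixel, rtol=1e-6
        )

    def test_poisson_sampling_is_unbiased(self):
        cfg = ef.reduced_config(12, 32, sample_rsd=0.0, pixel_noise_sd=0.0,
                                boundary_waviness_amplitude=0.0,
                                epithelium_thickness_mean=150.0,
                                epithelium_thickness_sd=0.0)
        rng = np.random.default_rng(2)
        sample = ef.generate_sample("normal", cfg, rng, render=False)
        expected = ef.render_decay_cube(sample.true_tau2_map, cfg, rng, poisson=False)
        yy, xx = np.nonzero(sample.roi_mask)
        y0, x0 = yy[0], xx[0]
        mu = expected[y0, x0]
        renders = np.array(
            [
                ef.render_decay_cube(sample.true_tau2_map, cfg, rng)[y0, x0]
                for _ in range(1000)
            ],
            dtype=float,
        )
        se = np.sqrt(mu / 1000).clip(min=1e-9)
        assert np.all(np.abs(renders.mean(axis=0) - mu) < 3.5 * se + 1e-6)

    def test_counts_nonnegative_integers(self, desk_config):
        sample = ef.generate_sample("CIN3", desk_config, np.random.default_rng(3))
        assert sample.decay_cube.dtype == np.uint16
        assert sample.decay_cube.min() >= 0


class TestGeneratePool:
    def test_default_pool_is_32_samples_10_8_6_8(self, desk_config):
        pool = ef.generate_pool(desk_config, seed=0, render=False)
        assert len(pool) == 32
        counts = {c: sum(s.label == c for s in pool) for c in ef.PATHOLOGY_CLASSES}
        assert counts == {"normal": 10, "CIN1": 8, "CIN2": 6, "CIN3": 8}

    def test_pool_deterministic_given_seed(self):
        cfg = ef.reduced_config(24, 24)
        a = ef.generate_pool(cfg, seed=42)
        b = ef.generate_pool(cfg, seed=42)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.decay_cube, s2.decay_cube)
            np.testing.assert_array_equal(s1.true_layer_means, s2.true_layer_means)

    def test_singleton_pool_covers_all_labels(self, desk_config):
        desk_config.pool_counts = {c: 1 for c in ef.PATHOLOGY_CLASSES}
        pool = ef.generate_pool(desk_config, seed=1, render=False)
        assert sorted(s.label for s in pool) == sorted(ef.PATHOLOGY_CLASSES)

    def test_roi_tau2_finite_exactly_on_roi(self, desk_config):
        sample = ef.generate_sample("CIN1", desk_config, np.random.default_rng(9),
                                    render=False)
        finite = np.isfinite(sample.true_tau2_map)
        np.testing.assert_array_equal(finite, sample.roi_mask)
        assert sample.true_tau2_map[finite].min() > 0

    def test_noiseless_whole_roi_means_in_printed_ranges(self):
        cfg = ef.reduced_config(48, 48, sample_rsd=0.0, pixel_noise_sd=0.0)
        rng = np.random.default_rng(0)
        normal = ef.generate_sample("normal", cfg, rng, render=False)
        assert 670 <= np.nanmean(normal.true_tau2_map) <= 1000
        for label in ef.PRECANCER_CLASSES:
            s = ef.generate_sample(label, cfg, rng, render=False)
            assert 450 <= np.nanmean(s.true_tau2_map) <= 850


def test_sample_roundtrip_via_tiff_and_sidecar(tmp_path, desk_config):
    sample = ef.generate_sample(
        "CIN2", desk_config, np.random.default_rng(4), sample_id="CIN2_00"
    )
    sample.save(tmp_path, desk_config)
    loaded, meta = ef.GroundTruthSample.load(tmp_path, "CIN2_00")
    np.testing.assert_array_equal(loaded.decay_cube, sample.decay_cube)
    assert meta["label"] == "CIN2"
    assert meta["bin_width_ps"] == pytest.approx(desk_config.bin_width)
    np.testing.assert_allclose(loaded.true_layer_means, sample.true_layer_means)
    np.testing.assert_allclose(loaded.geometry.membrane, sample.geometry.membrane)
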