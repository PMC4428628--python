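"""Decay fitting: threshold, IRF estimation, bi-exponential NLLS."""

import numpy as np
import pytest
from scipy.stats import norm

import epiflim as ef
from epiflim.decay import (
    DegenerateIRFError,
    TAU1_BOUNDS,
    TAU2_BOUNDS,
    fit_channel_range,
    refine_irf,
)

N_BINS = 256
BIN_W = 10_000.0 / N_BINS  # ps
TIMES = (np.arange(N_BINS) + 0.5) * BIN_W


def make_curve(tau2=800.0, tau1=30.0, f1=0.2, photons=5000, center=1000.0,
               sigma=40.0, rng=None):
    """Poisson-sampled two-component decay at the canonical acquisition."""
    b1 = ef.exgauss_basis(TIMES, tau1, center, sigma)
    b2 = ef.exgauss_basis(TIMES, tau2, center, sigma)
    expected = photons * (f1 * b1 + (1 - f1) * b2)
    counts = expected if rng is None else rng.poisson(expected)
    return ef.DecayCurve(counts.astype(float), BIN_W), expected


def grid_search_oracle(curve, irf, n1=40, n2=60):
    """Brute-force chi2 minimization over a (tau1, tau2) log grid with
    weighted linear amplitudes per grid point.  Independent of the NLLS
    code path; returns (tau1, tau2, log-step of the tau2 grid)."""
    sl = fit_channel_range(curve.counts)
    y = np.asarray(curve.counts, float)[sl]
    t = curve.times[sl]
    w = 1.0 / np.maximum(y, 1.0)
    g1 = np.geomspace(*TAU1_BOUNDS, n1)
    g2 = np.geomspace(*TAU2_BOUNDS, n2)
    best = (np.inf, None, None)
    for tau1 in g1:
        b1 = ef.exgauss_basis(t, tau1, *irf)
        for tau2 in g2:
            b2 = ef.exgauss_basis(t, tau2, *irf)
            A = np.column_stack([b1, b2]) * np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
            coef = np.maximum(coef, 0.0)
            resid = y - coef[0] * b1 - coef[1] * b2
            chi2 = float(w @ resid**2)
            if chi2 < best[0]:
                best = (chi2, tau1, tau2)
    return best[1], best[2], np.log(g2[1] / g2[0])


class TestPhotonThreshold:
    def test_49_excluded_50_included(self):
        mask = ef.apply_photon_threshold(np.array([[49, 50, 51]]), 50)
        np.testing.assert_array_equal(mask, [[False, True, True]])

    def test_zero_threshold_includes_all(self):
        mask = ef.apply_photon_threshold(np.zeros((4, 4)), 0)
        assert mask.all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ef.apply_photon_threshold(np.zeros((2, 2)), -1)


class TestEstimateIRF:
    def test_gaussian_cdf_step_recovers_sigma(self):
        # rising edge = Gaussian CDF; plateau afterwards
        center, sigma = 2000.0, 120.0
        counts = 1000 * norm.cdf(TIMES, loc=center, scale=sigma)
        est_center, est_sigma = ef.estimate_irf(ef.DecayCurve(counts, BIN_W))
        assert abs(est_center - center) < BIN_W
        assert abs(est_sigma - sigma) < BIN_W

    def test_recovery_on_synthetic_decay(self):
        rng = np.random.default_rng(0)
        curve, _ = make_curve(photons=200_000, rng=rng)
        center, sigma = ef.estimate_irf(curve)
        assert abs(center - 1000.0) < 2 * BIN_W
        assert abs(sigma - 40.0) < 0.5 * 40.0

    def test_flat_curve_rejected(self):
        with pytest.raises(DegenerateIRFError):
            ef.estimate_irf(ef.DecayCurve(np.full(64, 5.0), BIN_W))

    def test_monotone_decreasing_curve_rejected(self):
        with pytest.raises(DegenerateIRFError):
            ef.estimate_irf(ef.DecayCurve(np.exp(-np.arange(64) / 8.0), BIN_W))

    def test_refinement_recovers_center_at_coarse_binning(self):
        rng = np.random.default_rng(1)
        nb = 64
        bw = 10_000.0 / nb
        t = (np.arange(nb) + 0.5) * bw
        b = ef.exgauss_basis(t, 800.0, 1000.0, 40.0)
        curve = ef.DecayCurve(rng.poisson(2e6 * b).astype(float), bw)
        center, _ = refine_irf(curve, ef.estimate_irf(curve))
        assert abs(center - 1000.0) < 0.5 * bw


class TestFitBiexponential:
    def test_noiseless_single_exponential_is_exact(self):
        counts = 5000 * ef.exgauss_basis(TIMES, 800.0, 0.0, 0.0)
        fit = ef.fit_biexponential(ef.DecayCurve(counts, BIN_W), irf=(0.0, 0.0))
        assert fit.converged
        assert fit.tau2 == pytest.approx(800.0, abs=1.0)
        assert fit.a1 == pytest.approx(0.0, abs=0.02)

    def test_amplitude_invariance(self):
        counts = ef.exgauss_basis(TIMES, 900.0, 1000.0, 40.0) * 3000 \
            + ef.exgauss_basis(TIMES, 30.0, 1000.0, 40.0) * 1000
        irf = (1000.0, 40.0)
        base = ef.fit_biexponential(ef.DecayCurve(counts, BIN_W), irf)
        for scale in (2.0, 10.0):
            scaled = ef.fit_biexponential(ef.DecayCurve(counts * scale, BIN_W), irf)
            assert scaled.tau2 == pytest.approx(base.tau2, rel=0.02)
            assert scaled.tau1 == pytest.approx(base.tau1, rel=0.2)

    def test_component_ordering(self):
        rng = np.random.default_rng(5)
        curve, _ = make_curve(rng=rng)
        fit = ef.fit_biexponential(curve, (1000.0, 40.0))
        assert fit.tau1 < fit.tau2
        assert fit.a1 >= 0 and fit.a2 >= 0

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        irf = (1000.0, 40.0)
        for _ in range(15):
            tau2 = rng.uniform(400, 1500)
            curve, _ = make_curve(tau2=tau2, rng=rng)
            fit = ef.fit_biexponential(curve, irf)
            _, tau2_oracle, step = grid_search_oracle(curve, irf)
            assert abs(np.log(fit.tau2 / tau2_oracle)) <= 2 * step

    def test_chi2_near_unity_for_well_exposed_pixels(self):
        rng = np.random.default_rng(3)
        irf = (1000.0, 40.0)
        chi2 = np.array(
            [ef.fit_biexponential(make_curve(rng=rng)[0], irf).chi2_reduced
             for _ in range(60)]
        )
        # ~85 effective channels: the weighted statistic has sd ~0.15 plus
        # heavy small-count tails, so the band reflects chi2 sampling theory
        assert 0.85 <= np.median(chi2) <= 1.2
        assert np.mean((chi2 >= 0.7) & (chi2 <= 1.4)) >= 0.90


class TestFitImage:
    def test_subthreshold_cube_has_no_valid_pixels(self, desk_config):
        cube = np.ones((8, 8, desk_config.n_time_bins), dtype=np.uint16)
        img = ef.fit_image(cube, bin_width=desk_config.bin_width, threshold=50)
        assert img.valid_mask.sum() == 0

    def test_fast_and_exact_methods_agree(self):
        rng = np.random.default_rng(8)
        nb = 128
        bw = 10_000.0 / nb
        t = (np.arange(nb) + 0.5) * bw
        cube = np.empty((3, 3, nb), dtype=np.uint16)
        taus = rng.uniform(500, 1200, 9)
        for i, tau in enumerate(taus):
            b = 0.2 * ef.exgauss_basis(t, 30.0, 1000.0, 40.0) \
                + 0.8 * ef.exgauss_basis(t, tau, 1000.0, 40.0)
            cube[i // 3, i % 3] = rng.poisson(20_000 * b)
        irf = (1000.0, 40.0)
        fast = ef.fit_image(cube, bw, irf=irf, method="fast")
        exact = ef.fit_image(cube, bw, irf=irf, method="exact")
        np.testing.assert_allclose(fast.tau2_map, exact.tau2_map, rtol=0.03)

    def test_intensity_scaling_leaves_tau2_unchanged(self):
        # lifetime is amplitude-invariant: doubling all counts of a
        # noiseless cube must not move the fitted tau2
        nb = 128
        bw = 10_000.0 / nb
        t = (np.arange(nb) + 0.5) * bw
        b = 0.2 * ef.exgauss_basis(t, 30.0, 1000.0, 40.0) \
            + 0.8 * ef.exgauss_basis(t, 800.0, 1000.0, 40.0)
        cube1 = np.broadcast_to(np.round(5000 * b), (2, 2, nb)).astype(np.uint16)
        cube2 = (2 * cube1.astype(np.uint32)).astype(np.uint16)
        irf = (1000.0, 40.0)
        img1 = ef.fit_image(cube1, bw, irf=irf)
        img2 = ef.fit_image(cube2, bw, irf=irf)
        np.testing.assert_allclose(img1.tau2_map, img2.tau2_map, rtol=0.01)

    def test_end_to_end_recovery_on_synthetic_sample(self, desk_config):
        sample = ef.generate_sample("normal", desk_config, np.random.default_rng(2))
        img = ef.fit_image(
            sample.decay_cube, desk_config.bin_width,
            threshold=desk_config.photon_threshold,
        )
        m = img.valid_mask & sample.roi_mask
        fitted = img.tau2_map[m].mean()
        true = sample.true_tau2_map[m]
        assert abs(fitted - true.mean()) < 3 * true.std() / np.sqrt(m.sum()) + 10

    def test_valid_pixels_bounded_by_threshold_count(self, desk_config):
        sample = ef.generate_sample("CIN1", desk_config, np.random.default_rng(6))
        img = ef.fit_image(sample.decay_cube, desk_config.bin_width, threshold=50)
        assert img.valid_mask.sum() <= (img.photon_map >= 50).sum()


def test_lifetime_image_tiff_roundtrip(tmp_path):
    tau2 = np.array([[800.0, np.nan], [900.0, 1000.0]])
    img = ef.LifetimeImage(
        tau2_map=tau2,
        photon_map=np.array([[100, 10], [200, 300]], dtype=float),
        valid_mask=np.isfinite(tau2),
        pixel_size=1.8,
    )
    path = tmp_path / "lt.tif"
    img.to_tiff(path)
    loaded = ef.LifetimeImage.from_tiff(path, pixel_size=1.8)
    np.testing.assert_allclose(loaded.tau2_map, np.float32(tau2))
    np.testing.assert_array_equal(loaded.valid_mask, img.valid_mask)
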