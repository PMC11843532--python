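import math

import numpy as np
import pytest

from rotorlife.acquisition import (
    AcquisitionConfig,
    DecayHistogram,
    DecayModel,
    IRFProfile,
    expected_curve,
    make_gaussian_irf,
    simulate_decay,
    sum_pixel_decays,
)
from rotorlife.fit import fit_decay


class TestAcquisitionConfig:
    def test_angular_frequency_is_2pi_f(self):
        cfg = AcquisitionConfig(rep_rate_mhz=80.0, n_bins=64)
        assert cfg.angular_frequency == 2 * math.pi * 80.0 / 1000.0
        assert cfg.window_ns == pytest.approx(12.5)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(rep_rate_mhz=0), dict(rep_rate_mhz=-1), dict(n_bins=8), dict(window_ns=-2.0)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionConfig(**{"rep_rate_mhz": 80.0, "n_bins": 64, **kwargs})


class TestDecayModel:
    def test_components_sorted_by_lifetime(self):
        m = DecayModel([(0.3, 2.0), (0.7, 0.5)])
        assert m.lifetimes.tolist() == [0.5, 2.0]
        assert m.amplitudes.tolist() == [0.7, 0.3]

    @pytest.mark.parametrize(
        "components", [[], [(-0.1, 1.0)], [(1.0, 0.0)], [(0.0, 1.0)]]
    )
    def test_invalid_models_rejected(self, components):
        with pytest.raises(ValueError):
            DecayModel(components)


class TestGaussianIRF:
    def test_normalized_and_peaked_at_center(self, cfg):
        irf = make_gaussian_irf(0.2, 1.0, cfg)
        assert irf.weights.sum() == pytest.approx(1.0, abs=1e-12)
        peak_time = irf.bin_centers[irf.peak_bin]
        assert abs(peak_time - 1.0) <= cfg.bin_width_ns

    def test_empirical_fwhm_matches_request(self, cfg):
        # independent oracle: brute-force scan for half-maximum crossings
        irf = make_gaussian_irf(0.2, 1.0, cfg)
        w = irf.weights
        t = irf.bin_centers
        half = w.max() / 2
        above = np.nonzero(w >= half)[0]
        lo, hi = above[0], above[-1]
        # interpolate the half-maximum crossings on both flanks
        t_lo = np.interp(half, [w[lo - 1], w[lo]], [t[lo - 1], t[lo]])
        t_hi = np.interp(half, [w[hi + 1], w[hi]], [t[hi + 1], t[hi]])
        fwhm = t_hi - t_lo
        assert abs(fwhm - 0.2) <= cfg.bin_width_ns

    def test_nonpositive_fwhm_rejected(self, cfg):
        with pytest.raises(ValueError):
            make_gaussian_irf(0.0, 1.0, cfg)
        with pytest.raises(ValueError):
            make_gaussian_irf(-0.5, 1.0, cfg)

    def test_irf_must_be_normalized(self, cfg):
        with pytest.raises(ValueError):
            IRFProfile(bin_centers=cfg.bin_centers, weights=np.ones(cfg.n_bins))


class TestExpectedCurve:
    def test_delta_irf_gives_geometric_tail_sum(self, cfg, delta_irf, mono_tau1):
        # closed form: sum over prior pulses of exp(-(t+kT)/tau)
        curve = expected_curve(mono_tau1, delta_irf, cfg)
        t = cfg.bin_centers
        expected = np.exp(-t / 1.0) / (1.0 - math.exp(-cfg.period_ns / 1.0))
        assert np.allclose(curve, expected, rtol=1e-9)

    def test_linear_in_amplitude(self, cfg, irf):
        base = expected_curve(DecayModel([(1.0, 0.8)]), irf, cfg)
        scaled = expected_curve(DecayModel([(3.5, 0.8)]), irf, cfg)
        assert np.allclose(scaled, 3.5 * base, rtol=1e-12)

    def test_superposition_of_components(self, cfg, irf):
        m1 = DecayModel([(0.6, 0.3)])
        m2 = DecayModel([(0.4, 2.0)])
        both = DecayModel([(0.6, 0.3), (0.4, 2.0)])
        assert np.allclose(
            expected_curve(both, irf, cfg),
            expected_curve(m1, irf, cfg) + expected_curve(m2, irf, cfg),
            rtol=1e-12,
        )

    def test_long_period_converges_to_single_pulse(self):
        # period = 20*tau: periodic wrap deviates < 1e-6 from the plain
        # linear convolution (independent oracle via np.convolve)
        tau = 1.0
        cfg = AcquisitionConfig(rep_rate_mhz=1000.0 / (20 * tau), n_bins=2048)
        irf = make_gaussian_irf(0.1, 0.5, cfg)
        model = DecayModel([(1.0, tau)])
        periodic = expected_curve(model, irf, cfg)
        single = np.convolve(np.exp(-cfg.bin_centers / tau), irf.weights)[: cfg.n_bins]
        # compare where the curve is non-negligible
        mask = single > single.max() * 1e-2
        rel = np.abs(periodic[mask] - single[mask]) / single[mask]
        assert rel.max() < 1e-6

    def test_mismatched_binning_rejected(self, cfg, mono_tau1):
        other = AcquisitionConfig(rep_rate_mhz=80.0, n_bins=512)
        bad_irf = make_gaussian_irf(0.2, 1.0, other)
        with pytest.raises(ValueError):
            expected_curve(mono_tau1, bad_irf, cfg)


class TestSimulateDecay:
    def test_zero_photons_gives_empty_histogram(self, cfg, irf, mono_tau1):
        h = simulate_decay(mono_tau1, irf, cfg, 0, seed=1)
        assert h.counts.sum() == 0

    def test_total_counts_concentrate_around_budget(self, cfg, irf, mono_tau1):
        for seed in range(5):
            h = simulate_decay(mono_tau1, irf, cfg, 10**6, seed=seed)
            assert 0.99 <= h.counts.sum() / 10**6 <= 1.01

    def test_same_seed_reproduces_histogram(self, cfg, irf, mono_tau1):
        h1 = simulate_decay(mono_tau1, irf, cfg, 10**5, seed=42)
        h2 = simulate_decay(mono_tau1, irf, cfg, 10**5, seed=42)
        assert np.array_equal(h1.counts, h2.counts)

    def test_negative_budget_rejected(self, cfg, irf, mono_tau1):
        with pytest.raises(ValueError):
            simulate_decay(mono_tau1, irf, cfg, -1, seed=0)

    def test_per_bin_poisson_mean_matches_expectation(self):
        # 200 seeds: bin-wise mean within 4 standard errors for >= 99% of bins
        cfg = AcquisitionConfig(rep_rate_mhz=80.0, n_bins=256)
        irf = make_gaussian_irf(0.3, 1.0, cfg)
        model = DecayModel([(1.0, 0.8)])
        photons = 20_000
        curve = expected_curve(model, irf, cfg)
        lam = curve * photons / curve.sum()
        counts = np.array(
            [simulate_decay(model, irf, cfg, photons, seed=s).counts for s in range(200)]
        )
        se = np.sqrt(lam / 200)
        ok = np.abs(counts.mean(axis=0) - lam) <= 4 * np.maximum(se, 1e-12)
        assert ok.mean() >= 0.99


class TestSumPixelDecays:
    def test_single_pixel_identity(self, cfg, irf, mono_tau1):
        h = simulate_decay(mono_tau1, irf, cfg, 10**4, seed=0)
        s = sum_pixel_decays([h])
        assert np.array_equal(s.counts, h.counts)

    def test_two_identical_pixels_double_counts(self, cfg, irf, mono_tau1):
        h = simulate_decay(mono_tau1, irf, cfg, 10**4, seed=0)
        s = sum_pixel_decays([h, h])
        assert np.array_equal(s.counts, 2 * h.counts)
        assert s.meta["n_pixels"] == 2

    def test_heterogeneous_configs_rejected(self, cfg, irf, mono_tau1):
        other_cfg = AcquisitionConfig(rep_rate_mhz=80.0, n_bins=512)
        other_irf = make_gaussian_irf(0.2, 1.0, other_cfg)
        h1 = simulate_decay(mono_tau1, irf, cfg, 10**3, seed=0)
        h2 = simulate_decay(mono_tau1, other_irf, other_cfg, 10**3, seed=0)
        with pytest.raises(ValueError):
            sum_pixel_decays([h1, h2])

    def test_summed_pixels_recover_lifetime(self, cfg, irf, mono_tau1):
        # 100 pixels of 1000 photons each: fit of the sum recovers tau to 2%
        pixels = [
            simulate_decay(mono_tau1, irf, cfg, 1000, seed=s) for s in range(100)
        ]
        pooled = sum_pixel_decays(pixels)
        res = fit_decay(pooled, irf, n=1)
        assert res.model.lifetimes[0] == pytest.approx(1.0, rel=0.02)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            sum_pixel_decays([])


class TestDecayHistogramValidation:
    def test_negative_counts_rejected(self, cfg):
        counts = np.zeros(cfg.n_bins)
        counts[3] = -1
        with pytest.raises(ValueError):
            DecayHistogram(bin_centers=cfg.bin_centers, counts=counts, config=cfg)

    def test_wrong_length_rejected(self, cfg):
        with pytest.raises(ValueError):
            DecayHistogram(
                bin_centers=cfg.bin_centers[:-1],
                counts=np.zeros(cfg.n_bins - 1),
                config=cfg,
            )
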