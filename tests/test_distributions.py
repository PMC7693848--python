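"""Stream distributions: two-Gaussian fits, discretization, resolution statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiralfoil import distributions as dist
from spiralfoil.exceptions import SpiralfoilError
from spiralfoil.synth import SynthConfig, gen_intensity_profile

SIGMA = 15.8 / dist.FWHM_PER_SIGMA


def gaussian_pair(p1=100.0, p2=160.0, s=SIGMA):
    return (
        dist.StreamDistribution.from_gaussian(p1, s),
        dist.StreamDistribution.from_gaussian(p2, s),
    )


class TestResolution:
    def test_reference_streams_resolve_at_2_24(self):
        """Peaks 100/160 µm with 15.8 µm half-height widths: R = 2.24."""
        d1, d2 = gaussian_pair()
        res = dist.resolution(d1, d2)
        assert res.R == pytest.approx(1.18 * 60.0 / 31.6, rel=1e-12)
        assert round(res.R, 2) == 2.24

    def test_identical_peaks_give_zero(self):
        d1, d2 = gaussian_pair(120.0, 120.0)
        assert dist.resolution(d1, d2).R == 0.0

    def test_scaling_laws(self):
        d1, d2 = gaussian_pair(100.0, 160.0)
        base = dist.resolution(d1, d2).R
        d3, d4 = gaussian_pair(100.0, 220.0)          # doubled separation
        assert dist.resolution(d3, d4).R == pytest.approx(2 * base)
        d5, d6 = gaussian_pair(100.0, 160.0, 2 * SIGMA)  # doubled widths
        assert dist.resolution(d5, d6).R == pytest.approx(base / 2)

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance(self, shift):
        d1, d2 = gaussian_pair()
        d1s, d2s = gaussian_pair(100.0 + shift, 160.0 + shift)
        assert dist.resolution(d1s, d2s).R == pytest.approx(
            dist.resolution(d1, d2).R, rel=1e-9
        )

    def test_zero_width_rejected(self):
        d1 = dist.StreamDistribution(peak=100.0, fwhm=0.0)
        d2 = dist.StreamDistribution(peak=160.0, fwhm=0.0)
        with pytest.raises(SpiralfoilError):
            dist.resolution(d1, d2)

    def test_fwhm_sigma_identity(self):
        d = dist.StreamDistribution.from_gaussian(100.0, 10.0)
        assert d.fwhm == pytest.approx(2.3548200450309493 * 10.0, rel=1e-9)


class TestTwoGaussianFit:
    def test_noiseless_profile_recovers_generating_means(self):
        cfg = SynthConfig(seed=3, noise_sd=0.0)
        profile = gen_intensity_profile(cfg, n_samples=256)
        d1, d2 = dist.fit_two_gaussians(profile)
        assert d1.peak == pytest.approx(100.0, abs=0.1)
        assert d2.peak == pytest.approx(160.0, abs=0.1)
        assert d1.sigma == pytest.approx(SIGMA, rel=0.02)
        assert d2.sigma == pytest.approx(SIGMA, rel=0.02)

    def test_noisy_profile_recovers_peaks_near_100_and_160(self):
        cfg = SynthConfig(seed=11, noise_sd=0.02)
        d1, d2 = dist.fit_two_gaussians(gen_intensity_profile(cfg))
        assert d1.peak == pytest.approx(100.0, abs=2.0)
        assert d2.peak == pytest.approx(160.0, abs=2.0)

    def test_single_peak_profile_flagged_degenerate(self):
        x = np.linspace(0, 300, 128)
        y = np.exp(-0.5 * ((x - 130) / 12.0) ** 2)
        profile = dist.IntensityProfile(x, y)
        with pytest.warns(RuntimeWarning):
            d1, d2 = dist.fit_two_gaussians(profile)
        assert d1.degenerate and d2.degenerate

    def test_profile_validation(self):
        with pytest.raises(SpiralfoilError):
            dist.IntensityProfile(np.arange(8), np.arange(8))
        x = np.arange(20.0)
        x[5] = x[4]
        with pytest.raises(SpiralfoilError):
            dist.IntensityProfile(x, np.ones(20))


class TestDiscretize:
    def test_single_bin_sits_at_mean_with_unit_weight(self):
        d = dist.StreamDistribution.from_gaussian(100.0, SIGMA)
        out = dist.discretize(d, n_bins=1)
        assert out.bins.shape == (1, 2)
        assert out.bins[0, 0] == 100.0
        assert out.bins[0, 1] == 1.0

    def test_weights_symmetric_about_mean(self):
        d = dist.StreamDistribution.from_gaussian(150.0, 10.0)
        out = dist.discretize(d, n_bins=50, span_sigmas=3.0)
        w = out.bins[:, 1]
        assert np.allclose(w, w[::-1], atol=1e-12)

    @given(n=st.integers(3, 80), span=st.floats(0.5, 4.0))
    @settings(max_examples=40, deadline=None)
    def test_total_weight_is_one(self, n, span):
        d = dist.StreamDistribution.from_gaussian(150.0, 10.0)
        out = dist.discretize(d, n_bins=n, span_sigmas=span)
        assert out.bins[:, 1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_clipping_renormalizes_with_warning(self):
        d = dist.StreamDistribution.from_gaussian(10.0, 10.0)
        with pytest.warns(RuntimeWarning):
            out = dist.discretize(d, n_bins=30, clip=(0.0, 300.0))
        assert out.bins[:, 1].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.bins[:, 0].min() >= 0.0


class TestDownstreamDistribution:
    def test_point_mass_width_floors_at_bin_width(self):
        crossings = np.column_stack([np.full(10, 50.0), np.full(10, 0.1)])
        with pytest.warns(RuntimeWarning):
            d = dist.downstream_distribution(crossings, bin_width=2.0)
        assert d.fwhm == 2.0

    def test_gaussian_sample_peak_within_one_bin(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(120.0, 8.0, 4000)
        crossings = np.column_stack([pos, np.full(pos.size, 1.0 / pos.size)])
        d = dist.downstream_distribution(crossings, bin_width=2.0)
        assert d.peak == pytest.approx(120.0, abs=2.0)
        assert d.fwhm == pytest.approx(dist.FWHM_PER_SIGMA * 8.0, rel=0.25)

    def test_two_separated_clusters_resolve(self):
        c1 = np.column_stack([np.random.default_rng(1).normal(40, 1.5, 500),
                              np.full(500, 1e-3)])
        c2 = np.column_stack([np.random.default_rng(2).normal(250, 1.5, 500),
                              np.full(500, 1e-3)])
        d1 = dist.downstream_distribution(c1)
        d2 = dist.downstream_distribution(c2)
        assert dist.resolution(d1, d2).R > 1.0
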