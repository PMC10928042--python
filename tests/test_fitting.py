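"""Voxel-wise fitting: smoothing, round trips, oracles, whole-volume maps."""

import numpy as np
import pytest

from mbdwi import (
    AcquisitionProtocol, DkiParams, DwiVolume, FrocParams, IvimParams,
    SemParams, SignalDecay,
    compute_adc, extract_decay, fit_dki, fit_froc, fit_ivim, fit_sem,
    fit_volume, froc_composite, ivim_signal, sem_signal, smooth_volume,
)
from mbdwi.fitting import BOUNDS
from mbdwi.protocol import HIGH_B_SUBSET, IVIM_B_SUBSET

from conftest import decay_from_model, noisy_decay


class TestSmoothing:
    def _volume(self, data, protocol):
        return DwiVolume(data, protocol, voxel_size=(0.6, 0.6, 2.0))

    def test_constant_image_unchanged(self, protocol):
        vol = self._volume(np.full((8, 8, 2, 11), 37.0), protocol)
        out = smooth_volume(vol, fwhm=3.0)
        np.testing.assert_allclose(out.data, 37.0, rtol=1e-12)

    def test_fwhm_zero_is_identity(self, protocol):
        rng = np.random.default_rng(0)
        vol = self._volume(rng.uniform(1, 2, (6, 6, 1, 11)), protocol)
        assert smooth_volume(vol, 0.0) is vol

    def test_negative_fwhm_rejected(self, protocol):
        vol = self._volume(np.ones((4, 4, 1, 11)), protocol)
        with pytest.raises(ValueError):
            smooth_volume(vol, -1.0)

    def test_impulse_peak_matches_direct_convolution(self, protocol):
        # brute-force separable-kernel oracle, built independently of scipy
        fwhm, dx = 3.0, 0.6
        sigma = fwhm / np.sqrt(8 * np.log(2)) / dx
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        expected_peak = k1[radius] ** 2  # separable 2-D center weight

        data = np.zeros((33, 33, 1, 11))
        data[16, 16, 0, :] = 1.0
        out = smooth_volume(self._volume(data, protocol), fwhm)
        assert out.data[16, 16, 0, 0] == pytest.approx(expected_peak, rel=1e-10)

    def test_smoothing_is_in_plane_only(self, protocol):
        data = np.zeros((9, 9, 3, 11))
        data[4, 4, 1, :] = 1.0
        out = smooth_volume(self._volume(data, protocol), 3.0)
        assert out.data[:, :, 0, :].max() == 0.0
        assert out.data[:, :, 2, :].max() == 0.0


class TestExtractDecay:
    def test_normalises_by_voxel_s0(self, protocol):
        data = np.zeros((1, 1, 1, 11))
        data[0, 0, 0, :] = 200.0 * np.exp(-np.array(protocol.b_values) * 1e-3)
        dec = extract_decay(DwiVolume(data, protocol), (0, 0, 0))
        assert dec.s_rel[0] == 1.0
        np.testing.assert_allclose(
            dec.s_rel, np.exp(-np.array(protocol.b_values, float) * 1e-3), rtol=1e-12)

    def test_zero_s0_marks_voxel_unfittable(self, protocol):
        data = np.zeros((1, 1, 1, 11))
        assert extract_decay(DwiVolume(data, protocol), (0, 0, 0)) is None


TOLERANCES = {"ivim": 0.01, "dki": 0.001, "sem": 0.001}


class TestNoiselessRoundTrips:
    """Generate → fit recovers the truth for every model (identifiable params)."""

    def test_ivim_recovery(self):
        truth = IvimParams(d_t=0.5e-3, d_p=10e-3, f=0.03)
        dec = decay_from_model("ivim", truth, IVIM_B_SUBSET)
        fit = fit_ivim(dec)
        assert fit.d_t == pytest.approx(truth.d_t, rel=0.01)
        assert fit.d_p == pytest.approx(truth.d_p, rel=0.01)
        assert fit.f == pytest.approx(truth.f, rel=0.01)

    def test_ivim_degenerate_mono_exponential(self):
        truth = IvimParams(d_t=0.8e-3, d_p=0.8e-3, f=0.0)
        fit = fit_ivim(decay_from_model("ivim", truth, IVIM_B_SUBSET))
        assert fit.f <= 0.005
        assert fit.d_t == pytest.approx(truth.d_t, rel=0.001)

    def test_dki_recovery(self):
        truth = DkiParams(md=0.6e-3, mk=0.9)
        fit = fit_dki(decay_from_model("dki", truth, HIGH_B_SUBSET))
        assert fit.md == pytest.approx(truth.md, rel=0.001)
        assert fit.mk == pytest.approx(truth.mk, rel=0.001)

    def test_sem_alpha_one_limit(self):
        truth = SemParams(ddc=0.7e-3, alpha=1.0)
        fit = fit_sem(decay_from_model("sem", truth, HIGH_B_SUBSET))
        assert fit.alpha >= 0.999
        assert fit.ddc == pytest.approx(truth.ddc, rel=0.001)

    def test_froc_identifiable_parameters(self, protocol):
        truth = FrocParams(d=0.4e-3, beta=0.9, mu=6e-3)
        dec = decay_from_model("froc", truth, protocol.b_values, protocol)
        fr = fit_froc(dec, protocol)
        # β and the composite D·μ^{2(β−1)} are what the decay determines
        assert fr.params.beta == pytest.approx(truth.beta, rel=1e-6)
        assert fr.composite == pytest.approx(froc_composite(truth), rel=1e-6)
        assert fr.mu_identifiable is False

    def test_froc_beta_one_recovers_d_exactly(self, protocol):
        truth = FrocParams(d=0.6e-3, beta=1.0, mu=8e-3)
        fr = fit_froc(decay_from_model("froc", truth, protocol.b_values, protocol),
                      protocol)
        assert fr.params.beta == pytest.approx(1.0, abs=1e-6)
        assert fr.params.d == pytest.approx(truth.d, rel=0.001)

    def test_random_draws_respect_bounds_and_recover(self, protocol):
        rng = np.random.default_rng(20240312)
        for _ in range(25):
            truth = IvimParams(d_t=rng.uniform(3e-4, 1.2e-3),
                               d_p=rng.uniform(5e-3, 2e-2),
                               f=rng.uniform(0.02, 0.3))
            fit = fit_ivim(decay_from_model("ivim", truth, IVIM_B_SUBSET))
            assert BOUNDS["d_t"][0] <= fit.d_t <= BOUNDS["d_t"][1]
            assert fit.d_p >= fit.d_t
            assert 0 <= fit.f <= 1
            assert fit.d_t == pytest.approx(truth.d_t, rel=0.01)


class TestSemOfBiexponentialDecay:
    def test_two_compartment_truth_yields_alpha_below_one(self):
        truth = IvimParams(d_t=0.5e-3, d_p=10e-3, f=0.25)
        b = np.asarray(HIGH_B_SUBSET, dtype=float)
        dec = SignalDecay(b, ivim_signal(truth, b))
        fit = fit_sem(dec)
        assert fit.alpha < 1.0

        # brute-force grid oracle over (DDC, α)
        ddc_grid = np.linspace(1e-4, 1.5e-3, 150)
        alpha_grid = np.linspace(0.5, 1.0, 150)
        sse = np.array([
            [np.sum((np.exp(-(b * ddc) ** a) - dec.s_rel) ** 2) for a in alpha_grid]
            for ddc in ddc_grid
        ])
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        assert alpha_grid[j] < 1.0
        assert fit.ddc == pytest.approx(ddc_grid[i], abs=ddc_grid[1] - ddc_grid[0])
        assert fit.alpha == pytest.approx(alpha_grid[j], abs=alpha_grid[1] - alpha_grid[0])


class TestIvimUnderNoise:
    def test_median_f_within_half_of_truth_at_snr50(self, protocol):
        truth = IvimParams(d_t=0.5e-3, d_p=10e-3, f=0.03)
        b = np.asarray(IVIM_B_SUBSET, dtype=float)
        idx = protocol.subset_indices(IVIM_B_SUBSET)
        avgs = np.asarray(protocol.averages)[idx]
        s_rel = ivim_signal(truth, b)
        rng = np.random.default_rng(20240312)
        fits = []
        for _ in range(100):
            dec = noisy_decay(s_rel, b, snr=50, averages=avgs, rng=rng)
            p = fit_ivim(dec)
            assert 0 <= p.f <= 1 and p.d_p >= p.d_t > 0
            fits.append(p.f)
        median_f = float(np.median(fits))
        assert abs(median_f - truth.f) <= 0.5 * truth.f


class TestAdc:
    def test_mono_exponential_slope_exact(self):
        b = np.array([0.0, 200, 500, 800, 1000])
        dec = SignalDecay(b, np.exp(-b * 1.1e-3))
        assert compute_adc(dec) == pytest.approx(1.1e-3, rel=1e-12)

    def test_two_point_decay(self):
        dec = SignalDecay(np.array([0.0, 1000.0]), np.array([1.0, 0.4]))
        assert compute_adc(dec) == pytest.approx(-np.log(0.4) / 1000, rel=1e-12)

    def test_noisy_decay_matches_closed_form_regression(self):
        rng = np.random.default_rng(5)
        b = np.array([0.0, 150, 300, 500, 800, 1000])
        s = np.exp(-b * 0.9e-3) * np.exp(rng.normal(0, 0.02, b.size))
        s[0] = 1.0
        dec = SignalDecay(b, s)
        y = np.log(s)
        slope = ((b - b.mean()) * (y - y.mean())).sum() / ((b - b.mean()) ** 2).sum()
        assert compute_adc(dec) == pytest.approx(-slope, rel=1e-12)


class TestFitVolume:
    def test_piecewise_constant_phantom_region_medians(self, protocol):
        # two-region DKI phantom, noise-free: within-region medians equal truth
        inner = DkiParams(md=0.5e-3, mk=1.0)
        outer = DkiParams(md=0.7e-3, mk=0.6)
        b = np.asarray(protocol.b_values, dtype=float)
        data = np.zeros((10, 10, 1, 11))
        from mbdwi import dki_signal
        region = np.zeros((10, 10, 1), dtype=bool)
        region[3:7, 3:7, 0] = True
        data[region] = 500 * dki_signal(inner, b, warn_validity=False)
        data[~region] = 500 * dki_signal(outer, b, warn_validity=False)
        vol = DwiVolume(data, protocol)
        maps = {m.name: m for m in fit_volume(vol, "dki", fwhm=0.0)}
        md = maps["MD"].values[..., 0]
        mk = maps["MK"].values[..., 0]
        assert np.nanmedian(md[region[..., 0]]) == pytest.approx(0.5, rel=1e-3)
        assert np.nanmedian(mk[region[..., 0]]) == pytest.approx(1.0, rel=1e-3)
        assert np.nanmedian(md[~region[..., 0]]) == pytest.approx(0.7, rel=1e-3)

    def test_empty_mask_rejected(self, protocol):
        vol = DwiVolume(np.ones((4, 4, 1, 11)), protocol)
        with pytest.raises(ValueError):
            fit_volume(vol, "adc", mask=np.zeros((4, 4, 1), bool))

    def test_unknown_model_rejected(self, protocol):
        vol = DwiVolume(np.ones((2, 2, 1, 11)), protocol)
        with pytest.raises(ValueError):
            fit_volume(vol, "tensor")
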