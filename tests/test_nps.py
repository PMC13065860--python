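"""Noise power spectrum: scaling, profiles and anisotropy testing."""

import numpy as np
import pytest
from scipy import stats

from mammoiq import nps, synthetic
from mammoiq.imgio import ImageStack, centered_roi
from mammoiq.nps import Nps1D, Nps2D


def make_nps2d(values, spacing=(0.05, 0.05)):
    ny, nx = values.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=spacing[0]))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=spacing[1]))
    return Nps2D(values, fx, fy, spacing, n_noise_images=1)


class TestMakeNoiseImages:
    def test_identical_images_give_zero_noise(self):
        stack = ImageStack(np.full((4, 8, 8), 5.0), (0.05, 0.05))
        noise = nps.make_noise_images(stack)
        np.testing.assert_array_equal(noise.noise_images, 0.0)

    @pytest.mark.parametrize("scheme,n_expected", [("circular", 10),
                                                   ("independent", 5)])
    def test_noise_image_counts(self, rng, scheme, n_expected):
        stack = ImageStack(rng.standard_normal((10, 8, 8)), (0.05, 0.05))
        assert nps.make_noise_images(stack, scheme).noise_images.shape[0] == n_expected

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            nps.make_noise_images(ImageStack(np.zeros((1, 8, 8)), (0.05, 0.05)))


class TestNps2D:
    def test_zero_noise_gives_zero_nps(self):
        stack = ImageStack(np.full((4, 140, 140), 9.0), (0.05, 0.05))
        n2 = nps.compute_nps2d(nps.make_noise_images(stack),
                               centered_roi((140, 140), 128, 128))
        np.testing.assert_array_equal(n2.values, 0.0)

    def test_white_noise_level_matches_sigma2_dxdy(self):
        """Flat spectrum at sigma^2*dx*dy for i.i.d. Gaussian noise
        (Parseval); disjoint pairs keep the averaging independent."""
        sigma, d = 10.0, 0.05
        cfg = synthetic.FlatFieldConfig(shape_px=(128, 128), spacing_mm=d,
                                        noise_sd_adu=sigma, n_images=20, seed=3)
        stack, _ = synthetic.gen_flat_stack(cfg)
        noise = nps.make_noise_images(stack, "independent")
        n2 = nps.compute_nps2d(noise)
        expected = sigma**2 * d * d
        assert n2.values.mean() == pytest.approx(expected, rel=0.05)
        assert nps.nps_total_variance(n2) == pytest.approx(sigma**2, rel=0.05)

    def test_dc_bin_zero_after_mean_subtraction(self, rng):
        stack = ImageStack(rng.standard_normal((4, 128, 128)), (0.05, 0.05))
        n2 = nps.compute_nps2d(nps.make_noise_images(stack))
        dc = n2.values[np.argmin(np.abs(n2.fy)), np.argmin(np.abs(n2.fx))]
        assert dc == pytest.approx(0.0, abs=1e-20)

    def test_offset_invariance_and_quadratic_scaling(self, rng):
        px = rng.standard_normal((6, 128, 128))
        base = nps.compute_nps2d(nps.make_noise_images(
            ImageStack(px, (0.05, 0.05))))
        shifted = nps.compute_nps2d(nps.make_noise_images(
            ImageStack(px + 1000.0, (0.05, 0.05))))
        scaled = nps.compute_nps2d(nps.make_noise_images(
            ImageStack(3.0 * px, (0.05, 0.05))))
        # +1000 costs ~1e-13 of float precision per pixel before it cancels
        np.testing.assert_allclose(shifted.values, base.values,
                                   rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(scaled.values, 9.0 * base.values,
                                   rtol=1e-10, atol=1e-25)

    def test_frequency_axes_span_nyquist(self):
        stack = ImageStack(np.zeros((2, 128, 128)), (0.05, 0.05))
        n2 = nps.compute_nps2d(nps.make_noise_images(stack))
        assert n2.nyquist == (10.0, 10.0)
        assert n2.fx.min() == -10.0
        assert n2.fx[1] - n2.fx[0] == pytest.approx(1 / (128 * 0.05))


class TestTotalVariance:
    def test_flat_spectrum_closed_form(self):
        # level sigma^2*dx*dy over the whole band integrates back to sigma^2
        sigma, d, n = 7.0, 0.1, 64
        n2 = make_nps2d(np.full((n, n), sigma**2 * d * d), (d, d))
        assert nps.nps_total_variance(n2) == pytest.approx(sigma**2, rel=1e-12)

    def test_linearity(self):
        n2 = make_nps2d(np.ones((32, 32)))
        doubled = make_nps2d(2 * np.ones((32, 32)))
        assert nps.nps_total_variance(doubled) == pytest.approx(
            2 * nps.nps_total_variance(n2))

    def test_zero_spectrum(self):
        assert nps.nps_total_variance(make_nps2d(np.zeros((16, 16)))) == 0.0


class TestRadialProfile:
    def test_flat_spectrum_stays_flat(self):
        prof = nps.radial_profile(make_nps2d(np.ones((64, 64))))
        np.testing.assert_allclose(prof.values, 1.0)
        assert prof.freq[0] > 0  # DC excluded
        assert prof.freq[-1] <= 10.0

    def test_isotropic_exponential_recovered_at_bin_centers(self):
        n, d = 128, 0.05
        fy = np.fft.fftshift(np.fft.fftfreq(n, d=d))
        FX, FY = np.meshgrid(fy, fy)
        values = np.exp(-np.hypot(FX, FY))
        prof = nps.radial_profile(make_nps2d(values, (d, d)))
        # binning tolerance: exp varies across an annulus
        np.testing.assert_allclose(prof.values, np.exp(-prof.freq), rtol=0.05)

    def test_anisotropic_profile_equals_bruteforce_angular_average(self):
        n, d = 64, 0.1
        f = np.fft.fftshift(np.fft.fftfreq(n, d=d))
        FX, FY = np.meshgrid(f, f)
        values = 1.0 + FX**2  # varies only with fx
        n2 = make_nps2d(values, (d, d))
        bw = 1.0 / (n * d)
        prof = nps.radial_profile(n2, bin_width=bw)
        # brute force: average grid samples per annulus
        fr = np.hypot(FX, FY)
        for fc, v in zip(prof.freq, prof.values):
            sel = (fr > 0) & (np.round(fr / bw) == round(fc / bw))
            assert v == pytest.approx(values[sel].mean(), rel=1e-9)


class TestAxisProfile:
    def test_flat_spectrum_flat_profiles(self):
        n2 = make_nps2d(np.ones((64, 64)))
        for direction in ("x", "y"):
            prof = nps.axis_profile(n2, direction)
            np.testing.assert_allclose(prof.values, 1.0)

    def test_fx_only_spectrum_reproduced_along_x(self):
        n, d = 64, 0.1
        f = np.fft.fftshift(np.fft.fftfreq(n, d=d))
        FX, _ = np.meshgrid(f, f)
        g = 1.0 + np.abs(FX)
        prof = nps.axis_profile(make_nps2d(g, (d, d)), "x")
        np.testing.assert_allclose(prof.values, 1.0 + prof.freq, rtol=1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nps.axis_profile(make_nps2d(np.ones((32, 32))), "x",
                             band_halfwidth=0, exclude_axis=True)


class TestAnisotropy:
    def test_identical_profiles_ratio_one(self):
        f = np.linspace(0.5, 5, 10)
        p = Nps1D(f, np.full(10, 2.0), "x", np.ones(10, int))
        r = Nps1D(f, np.full(10, 2.0), "radial", np.ones(10, int))
        np.testing.assert_allclose(nps.anisotropy_ratios(p, r).values, 1.0)

    def test_isotropic_noise_ratios_near_one(self):
        cfg = synthetic.FlatFieldConfig(shape_px=(140, 140), noise_sd_adu=10.0,
                                        n_images=20, seed=9)
        stack, _ = synthetic.gen_flat_stack(cfg)
        n2 = nps.compute_nps2d(nps.make_noise_images(stack, "independent"),
                               centered_roi((140, 140), 128, 128))
        radial = nps.radial_profile(n2)
        for direction in ("x", "y"):
            ratios = nps.anisotropy_ratios(nps.axis_profile(n2, direction), radial)
            assert abs(np.log(ratios.values).mean()) < 0.1

    def test_lowpass_along_x_pushes_ratios_apart(self):
        """Smoothing the noise along x suppresses high-fx power: the x/radial
        ratio dips below 1 at high frequency, the y/radial ratio rises."""
        cfg = synthetic.FlatFieldConfig(shape_px=(140, 140), noise_sd_adu=10.0,
                                        color_sigma_mm=(0.0, 0.12),
                                        n_images=20, seed=9)
        stack, _ = synthetic.gen_flat_stack(cfg)
        n2 = nps.compute_nps2d(nps.make_noise_images(stack, "independent"),
                               centered_roi((140, 140), 128, 128))
        radial = nps.radial_profile(n2)
        rx = nps.anisotropy_ratios(nps.axis_profile(n2, "x"), radial)
        ry = nps.anisotropy_ratios(nps.axis_profile(n2, "y"), radial)
        hi = rx.freq > 0.6 * rx.freq[-1]
        assert rx.values[hi].mean() < 0.8
        assert ry.values[hi].mean() > 1.1

    def test_constant_ratio_rejects(self):
        f = np.linspace(0.5, 5, 20)
        ratios = Nps1D(f, np.full(20, 1.5), "x", np.ones(20, int))
        _, p = nps.anisotropy_test(ratios)
        assert p < 0.05

    def test_degenerate_all_ones_raises(self):
        f = np.linspace(0.5, 5, 10)
        with pytest.raises(ValueError):
            nps.anisotropy_test(Nps1D(f, np.ones(10), "x", np.ones(10, int)))

    def test_null_calibration(self, rng):
        """Type-I error of the signed-rank test is ~5% at alpha = 0.05 for
        log-ratios symmetric about 0."""
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            ratios = np.exp(rng.normal(0, 0.2, size=20))
            _, p = nps.anisotropy_test(
                Nps1D(np.arange(1, 21.0), ratios, "x", np.ones(20, int)))
            rejections += p < 0.05
        rate = rejections / n_sims
        # binomial 3-sigma band around 0.05
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sims) + 0.005
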