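"""Slanted-edge MTF chain: detection, angle, ESF, erf fit, LSF, MTF."""

import numpy as np
import pytest
from scipy import integrate, special

from mammoiq import mtf, synthetic
from mammoiq.mtf import EdgeImage, Esf, ErfFit


def edge_image(angle=1.0, sigma=0.10, noise=0.0, side=256, spacing=0.05,
               seed=0, n=1, contrast=500.0):
    cfg = synthetic.EdgePhantomConfig(
        shape_px=(side, side), spacing_mm=spacing, angle_deg=angle,
        psf_sigma_mm=sigma, edge_contrast_adu=contrast, background_adu=500.0,
        noise_sd_adu=noise, n_images=n, seed=seed)
    stack, truth = synthetic.gen_edge_stack(cfg)
    return stack, truth


class TestDetectEdge:
    def test_noise_free_edge_positions_colinear(self):
        stack, _ = edge_image(angle=1.54)
        img = EdgeImage(stack.pixels[0], stack.pixel_spacing_mm)
        pos = mtf.detect_edge_positions(img)
        idx = np.arange(len(pos))
        fit = np.polyval(np.polyfit(idx, pos, 1), idx)
        assert np.abs(pos - fit).max() < 0.05

    def test_pure_noise_raises(self, rng):
        img = EdgeImage(rng.standard_normal((64, 64)), (0.05, 0.05))
        with pytest.raises(ValueError):
            mtf.detect_edge_positions(img)

    def test_shift_equivariance(self):
        stack, _ = edge_image(angle=1.0)
        img = stack.pixels[0]
        a = mtf.detect_edge_positions(EdgeImage(img, (0.05, 0.05)))
        # dropping the first 5 columns shifts every edge coordinate by -5
        b = mtf.detect_edge_positions(EdgeImage(img[:, 5:], (0.05, 0.05)))
        np.testing.assert_allclose(b, a - 5, atol=1e-6)


class TestEdgeAngle:
    @pytest.mark.parametrize("angle", [0.97, 1.54])
    def test_noise_free_recovery(self, angle):
        stack, _ = edge_image(angle=angle)
        pos = mtf.detect_edge_positions(
            EdgeImage(stack.pixels[0], stack.pixel_spacing_mm))
        est, _ = mtf.estimate_edge_angle(pos)
        assert est == pytest.approx(angle, abs=0.02)

    @pytest.mark.parametrize("angle", [0.97, 1.54])
    def test_recovery_with_one_percent_noise(self, angle):
        stack, _ = edge_image(angle=angle, noise=5.0, seed=3)
        pos = mtf.detect_edge_positions(
            EdgeImage(stack.pixels[0], stack.pixel_spacing_mm))
        est, _ = mtf.estimate_edge_angle(pos)
        assert est == pytest.approx(angle, abs=0.05)

    def test_axis_aligned_edge_gives_zero(self):
        pos = np.full(32, 17.25)
        est, _ = mtf.estimate_edge_angle(pos)
        assert est == 0.0


class TestCompositeEsf:
    def test_noise_free_esf_reproduces_generating_erf(self):
        stack, truth = edge_image(angle=1.2, sigma=0.10)
        esf = mtf.composite_esf(stack)
        # generating model: 500 + 500*Phi(d/sigma)
        expected = 500.0 + 500.0 * special.ndtr(esf.positions / 0.10)
        central = np.abs(esf.positions) < 1.0
        np.testing.assert_allclose(esf.values[central], expected[central],
                                   atol=2.0)

    def test_frame_pooling_reduces_noise(self):
        _, _ = edge_image()
        stack1, _ = edge_image(angle=1.0, noise=5.0, n=1, seed=7)
        stack10, _ = edge_image(angle=1.0, noise=5.0, n=10, seed=7)
        fit1 = mtf.fit_erf(mtf.composite_esf(stack1))
        fit10 = mtf.fit_erf(mtf.composite_esf(stack10))
        esf1 = mtf.composite_esf(stack1)
        esf10 = mtf.composite_esf(stack10)
        r1 = np.std(esf1.values - fit1(esf1.positions))
        r10 = np.std(esf10.values - fit10(esf10.positions))
        assert r10 < r1 / 2.0  # ~sqrt(10) expected

    def test_pixel_pitch_bins_on_axis_aligned_edge(self):
        cfg = synthetic.EdgePhantomConfig(angle_deg=0.0, noise_sd_adu=0.0,
                                          n_images=1)
        with pytest.warns(UserWarning):
            stack, _ = synthetic.gen_edge_stack(cfg)
        esf = mtf.composite_esf(stack, bin_width_px=1.0)
        steps = np.diff(esf.positions)
        np.testing.assert_allclose(steps, 0.05, atol=1e-9)


class TestErfFit:
    def test_exact_samples_recovered(self):
        x = np.linspace(-1, 1, 400)
        y = 100 + 50 * special.erf((x - 0.0) / (0.1 * np.sqrt(2)))
        fit = mtf.fit_erf(Esf(x, y, bin_width_mm=x[1] - x[0]))
        assert fit.offset == pytest.approx(100, rel=1e-6)
        assert fit.amplitude == pytest.approx(50, rel=1e-6)
        assert fit.edge_location_mm == pytest.approx(0.0, abs=1e-7)
        assert fit.sigma_mm == pytest.approx(0.1, rel=1e-6)

    def test_noisy_samples_sigma_within_2pct(self, rng):
        x = np.linspace(-1, 1, 800)
        y = 100 + 50 * special.erf(x / (0.1 * np.sqrt(2)))
        y = y + rng.normal(0, 1.0, size=x.shape)
        fit = mtf.fit_erf(Esf(x, y, bin_width_mm=x[1] - x[0]))
        assert fit.sigma_mm == pytest.approx(0.1, rel=0.02)

    def test_falling_edge_polarity(self):
        x = np.linspace(-1, 1, 400)
        y = 100 - 50 * special.erf(x / (0.1 * np.sqrt(2)))
        fit = mtf.fit_erf(Esf(x, y, bin_width_mm=x[1] - x[0]))
        assert fit.amplitude == pytest.approx(-50, rel=1e-5)
        assert fit.sigma_mm == pytest.approx(0.1, rel=1e-5)


class TestLsf:
    def test_analytic_lsf_is_gaussian_with_sigma(self):
        fit = ErfFit(100, 50, 0.0, 0.1)
        x, lsf = mtf.lsf_from_fit(fit, 0.005)
        # second moment of the normalized LSF = sigma^2
        w = lsf / lsf.sum()
        var = (w * x**2).sum()
        assert np.sqrt(var) == pytest.approx(0.1, rel=1e-4)

    def test_lsf_area_equals_esf_swing(self):
        fit = ErfFit(100, 50, 0.02, 0.1)
        x, lsf = mtf.lsf_from_fit(fit, 0.002)
        area = integrate.simpson(lsf, x=x)
        assert area == pytest.approx(2 * 50, rel=1e-6)

    def test_support_too_small_raises(self):
        with pytest.raises(ValueError, match="support"):
            mtf.lsf_from_fit(ErfFit(0, 1, 0, 0.1), 0.01, support_mm=0.3)


class TestMtfFromLsf:
    def test_gaussian_lsf_closed_form(self):
        sigma = 0.1
        dx = 0.0125
        x = np.arange(-80, 81) * dx
        lsf = np.exp(-(x**2) / (2 * sigma**2))
        curve = mtf.mtf_from_lsf(lsf, dx, nyquist=10.0)
        expected = np.exp(-2 * np.pi**2 * sigma**2 * curve.freq**2)
        np.testing.assert_allclose(curve.values, expected, atol=1e-4)

    def test_delta_lsf_gives_unity_mtf(self):
        lsf = np.zeros(65)
        lsf[32] = 1.0
        curve = mtf.mtf_from_lsf(lsf, 0.01)
        np.testing.assert_allclose(curve.values, 1.0)

    def test_normalized_at_zero(self):
        x = np.arange(-50, 51) * 0.01
        curve = mtf.mtf_from_lsf(np.exp(-(x**2) / (2 * 0.05**2)), 0.01)
        assert curve.values[0] == 1.0

    def test_undecayed_support_raises(self):
        lsf = np.ones(64)
        with pytest.raises(ValueError, match="decayed"):
            mtf.mtf_from_lsf(lsf, 0.01)


class TestFreqReadout:
    def test_gaussian_f50_closed_form(self):
        sigma, dx = 0.1, 0.005
        x = np.arange(-200, 201) * dx
        curve = mtf.mtf_from_lsf(np.exp(-(x**2) / (2 * sigma**2)), dx,
                                 nyquist=10.0)
        assert mtf.freq_at_mtf(curve, 0.5) == pytest.approx(
            mtf.gaussian_f50(sigma), rel=1e-3)
        assert mtf.gaussian_f50(0.1) == pytest.approx(1.874, abs=0.001)

    def test_level_one_gives_zero_frequency(self):
        x = np.arange(-50, 51) * 0.01
        curve = mtf.mtf_from_lsf(np.exp(-(x**2) / (2 * 0.05**2)), 0.01)
        assert mtf.freq_at_mtf(curve, 1.0) == 0.0

    def test_f10_exceeds_f50(self):
        x = np.arange(-50, 51) * 0.01
        curve = mtf.mtf_from_lsf(np.exp(-(x**2) / (2 * 0.05**2)), 0.01)
        assert mtf.freq_at_mtf(curve, 0.1) > mtf.freq_at_mtf(curve, 0.5)

    def test_unreached_level_returns_nyquist(self):
        x = np.arange(-200, 201) * 0.005
        curve = mtf.mtf_from_lsf(np.exp(-(x**2) / (2 * 0.02**2)), 0.005,
                                 nyquist=2.0)
        assert mtf.freq_at_mtf(curve, 0.1) == 2.0


class TestNyquist:
    @pytest.mark.parametrize("spacing,expected", [(0.05, 10.0), (0.10, 5.0),
                                                  (1.0, 0.5)])
    def test_values(self, spacing, expected):
        assert mtf.nyquist_frequency(spacing) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            mtf.nyquist_frequency(0.0)


class TestEndToEnd:
    def test_noise_free_f50_within_2pct(self):
        stack, truth = edge_image(angle=1.0, sigma=0.10)
        s = mtf.analyze_edge_stack(stack)
        assert s.f50 == pytest.approx(truth["f50"], rel=0.02)

    def test_noisy_f50_within_5pct(self):
        stack, truth = edge_image(angle=1.0, sigma=0.10, noise=5.0, n=10,
                                  seed=5)
        s = mtf.analyze_edge_stack(stack)
        assert s.f50 == pytest.approx(truth["f50"], rel=0.05)

    def test_invariance_to_polarity_gain_and_angle(self):
        ref = None
        for angle in (0.7, 1.5, 2.8):
            stack, _ = edge_image(angle=angle, sigma=0.10)
            f50 = mtf.analyze_edge_stack(stack).f50
            if ref is None:
                ref = f50
            assert f50 == pytest.approx(ref, rel=0.01)
        stack, _ = edge_image(angle=1.0, sigma=0.10)
        flipped = stack
        flipped.pixels[:] = 2000.0 - 3.0 * flipped.pixels
        assert mtf.analyze_edge_stack(flipped).f50 == pytest.approx(ref,
                                                                    rel=0.01)

    def test_refinement_insensitivity(self):
        """Halving the LSF sample spacing leaves the MTF readouts unchanged
        to ~1e-4 (the chain is resolution-converged)."""
        stack, _ = edge_image(angle=1.0, sigma=0.10)
        a = mtf.analyze_edge_stack(stack, lsf_oversample=4)
        b = mtf.analyze_edge_stack(stack, lsf_oversample=8)
        assert b.f50 == pytest.approx(a.f50, rel=1e-4)

    def test_dm_sharper_than_sm(self, dm, sm):
        """Finer pitch and tighter PSF give higher f50 and f10."""
        out = {}
        for pre in (dm, sm):
            stack, _ = synthetic.gen_edge_stack(
                pre.edge_config(angle_deg=1.2, n_images=5, seed=13))
            s = mtf.analyze_edge_stack(stack)
            out[pre.name] = s
        assert out["DM"].f50 > out["SM"].f50
        assert out["DM"].f10 > out["SM"].f10
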