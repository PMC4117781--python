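"""Detector reduction: q-calibration, azimuthal averaging, subtraction."""

import numpy as np
import pytest

from ncsaxs import (DetectorImage, ReductionGeometry, average_repeats,
                    azimuthal_average, normalize_and_subtract, q_of_pixel,
                    render_detector_images)
from ncsaxs.reduce import drift_statistics
from ncsaxs.scatter import ScatteringProfile, default_qgrid


@pytest.fixture(scope="module")
def geometry():
    return ReductionGeometry(beam_center=(97.0, 97.0))


class TestQCalibration:
    def test_beam_center_is_zero(self, geometry):
        assert q_of_pixel(geometry, (97.0, 97.0)) == 0.0

    def test_small_angle_limit(self, geometry):
        # q ~ 2 pi r / (lambda L) within 0.5% for r/L < 0.05
        r_mm = 40.0
        px = (97.0 + r_mm / geometry.pixel_size, 97.0)
        q = q_of_pixel(geometry, px)
        approx = 2 * np.pi * r_mm / (geometry.wavelength
                                     * geometry.sample_detector_distance)
        assert q == pytest.approx(approx, rel=0.005)

    def test_edge_q_inside_measured_band(self, geometry):
        # 10.6 keV, 1 m, r = 40 mm -> q ~ 0.215 1/A
        px = (97.0 + 40.0 / geometry.pixel_size, 97.0)
        assert q_of_pixel(geometry, px) == pytest.approx(0.215, abs=0.003)


class TestAzimuthalAverage:
    def test_uniform_image(self, geometry):
        img = DetectorImage(np.full((195, 195), 7.0))
        prof = azimuthal_average(img, geometry)
        np.testing.assert_allclose(prof.I, 7.0)
        np.testing.assert_allclose(prof.sigma, 0.0, atol=1e-9)

    def test_masked_half_preserves_mean_raises_sigma(self, geometry):
        rng = np.random.default_rng(0)
        img_full = DetectorImage(rng.poisson(100, (195, 195)).astype(float))
        mask = np.ones((195, 195), bool)
        mask[:, 98:] = False
        img_half = DetectorImage(img_full.counts, mask=mask)
        pf = azimuthal_average(img_full, geometry)
        ph = azimuthal_average(img_half, geometry)
        common = min(len(pf), len(ph))
        np.testing.assert_allclose(ph.I[:common], pf.I[:common], rtol=0.05)
        ratio = ph.sigma[5:common] / pf.sigma[5:common]
        assert np.median(ratio) == pytest.approx(np.sqrt(2), rel=0.15)

    def test_rotation_invariance_for_radial_input(self, geometry):
        rr = geometry.radius_grid((195, 195))
        img = DetectorImage(np.exp(-(rr / 20) ** 2) * 100)
        rot = DetectorImage(np.rot90(img.counts, 1))
        a = azimuthal_average(img, geometry)
        b = azimuthal_average(rot, geometry)
        np.testing.assert_allclose(a.I, b.I, rtol=1e-9)

    def test_fully_masked_rejected(self, geometry):
        img = DetectorImage(np.ones((10, 10)),
                            mask=np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            azimuthal_average(img, geometry)


class TestRenderRoundTrip:
    def _truth(self):
        q = default_qgrid(120)
        I = 1e4 * np.exp(-(q * 40) ** 2 / 3) + 10.0
        return ScatteringProfile(q, I, np.zeros_like(q))

    def test_noiseless_render_recovers_profile(self, geometry):
        truth = self._truth()
        img = render_detector_images(truth, geometry, flux=1.0,
                                     sample=False)
        prof = azimuthal_average(img, geometry)
        sel = (prof.q > truth.q[0] * 1.2) & (prof.q < truth.q[-1] * 0.9)
        expect = np.interp(prof.q[sel], truth.q,
                           truth.I * img.exposure)
        np.testing.assert_allclose(prof.I[sel], expect, rtol=0.005)

    def test_poisson_render_consistent_with_counting_stats(self, geometry):
        truth = self._truth()
        img = render_detector_images(truth, geometry, flux=10.0, seed=3)
        prof = azimuthal_average(img, geometry)
        sel = (prof.q > truth.q[0] * 1.2) & (prof.q < truth.q[-1] * 0.9) \
            & (prof.sigma > 0)
        expect = np.interp(prof.q[sel], truth.q, truth.I * img.exposure
                           * 10.0)
        z = (prof.I[sel] - expect) / prof.sigma[sel]
        assert np.mean(z ** 2) == pytest.approx(1.0, abs=0.35)

    def test_zero_profile_renders_dark_frame(self, geometry):
        q = default_qgrid(30)
        zero = ScatteringProfile(q, np.zeros_like(q), np.zeros_like(q))
        img = render_detector_images(zero, geometry, flux=5.0, seed=0)
        assert img.counts.sum() == 0

    def test_bad_flux_rejected(self, geometry):
        with pytest.raises(ValueError):
            render_detector_images(self._truth(), geometry, flux=0.0)


class TestSubtractionAndAveraging:
    def _profile(self, I, sig=0.1):
        q = default_qgrid(50)
        return ScatteringProfile(q, np.full_like(q, I),
                                 np.full_like(q, sig))

    def test_sample_equals_buffer_gives_zero(self):
        s = self._profile(5.0)
        out = normalize_and_subtract(s, s)
        np.testing.assert_allclose(out.I, 0.0)
        np.testing.assert_allclose(out.sigma, np.hypot(0.1, 0.1))

    def test_monitor_scaling(self):
        s = self._profile(10.0)
        b = self._profile(2.0)
        a = normalize_and_subtract(s.scaled(2.0), b, sample_monitor=2.0)
        ref = normalize_and_subtract(s, b)
        np.testing.assert_allclose(a.I, ref.I)

    def test_bad_monitor_rejected(self):
        s = self._profile(1.0)
        with pytest.raises(ValueError):
            normalize_and_subtract(s, s, sample_monitor=0.0)

    def test_average_repeats_reduces_noise(self, rng):
        q = default_qgrid(60)
        base = np.exp(-(q * 30) ** 2 / 3)
        reps = [ScatteringProfile(q, base * (1 + 0.05 * rng.standard_normal(
            len(q))), 0.05 * base) for _ in range(5)]
        avg = average_repeats(reps)
        np.testing.assert_allclose(avg.sigma, 0.05 * base / np.sqrt(5),
                                   rtol=1e-9)
        assert np.max(np.abs(avg.I - base) / base) < 0.1

    def test_single_profile_identity(self):
        p = self._profile(3.0)
        assert average_repeats([p]) is p

    def test_inconsistent_repeats_warn(self):
        a = self._profile(1.0, sig=0.01)
        b = self._profile(2.0, sig=0.01)
        with pytest.warns(UserWarning, match="inconsistent"):
            average_repeats([a, b])

    def test_drift_statistic_flags_changing_frames(self):
        q = default_qgrid(40)
        p1 = ScatteringProfile(q, np.exp(-(q * 40) ** 2 / 3),
                               np.zeros_like(q))
        p2 = ScatteringProfile(q, np.exp(-(q * 20) ** 2 / 3),
                               np.zeros_like(q))
        stats = drift_statistics([p1, p1, p2])
        assert stats[0] == pytest.approx(1.0)
        assert stats[2] < stats[1]
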