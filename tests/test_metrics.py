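"""Unit and property tests for the angiography metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk

from nir2a import metrics as am
from nir2a.errors import ProfileError, ValidationError


def make_roiset(signal_centers, background_centers, radius=3.0):
    return am.ROISet(
        tuple(am.ROI(c, radius) for c in signal_centers),
        tuple(am.ROI(c, radius) for c in background_centers),
    )


@pytest.fixture
def three_disk_image():
    """Three disks at 0.9 on a 0.3 background, plus disk-aligned ROIs."""
    img = np.full((80, 80), 0.3)
    centers = [(15, 15), (15, 64), (64, 40)]
    for c in centers:
        rr, cc = disk(c, 8, shape=img.shape)
        img[rr, cc] = 0.9
    rois = make_roiset(centers, [(40, 10), (40, 70), (70, 10)])
    return img, rois


class TestSBR:
    def test_arithmetic(self, three_disk_image):
        img, rois = three_disk_image
        res = am.compute_sbr(img, rois)
        assert res.sbr == pytest.approx(3.0, abs=1e-12)
        assert res.i_signal == pytest.approx(0.9)
        assert res.i_background == pytest.approx(0.3)

    def test_constant_image_is_unity(self):
        rois = make_roiset([(10, 10), (10, 40), (40, 25)],
                           [(60, 10), (60, 40), (40, 60)])
        assert am.compute_sbr(np.full((70, 70), 0.42), rois).sbr == 1.0

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None)
    def test_positive_scalar_invariance(self, scale):
        rois = make_roiset([(10, 10), (10, 40), (40, 25)],
                           [(60, 10), (60, 40), (40, 60)])
        rng = np.random.default_rng(0)
        img = rng.uniform(0.1, 1.0, (70, 70))
        base = am.compute_sbr(img, rois).sbr
        assert am.compute_sbr(img * scale, rois).sbr == pytest.approx(base)

    def test_roi_outside_image_rejected(self):
        rois = make_roiset([(2, 2), (10, 40), (40, 25)],
                           [(60, 10), (60, 40), (40, 60)])
        with pytest.raises(ValidationError):
            am.compute_sbr(np.ones((70, 70)), rois)

    def test_roiset_needs_three_and_three(self):
        with pytest.raises(ValidationError):
            am.ROISet((am.ROI((5, 5), 2),), (am.ROI((9, 9), 2),) * 3)


class TestAutoROIs:
    @pytest.fixture
    def straight_vessel(self):
        img = np.full((90, 90), 0.2)
        mask = np.zeros((90, 90), bool)
        mask[43:48, 8:82] = True
        img[mask] = 0.9
        return img, mask

    def test_signal_centers_on_mask(self, straight_vessel):
        img, mask = straight_vessel
        rois = am.auto_rois(img, mask, min_background_distance=6, seed=0)
        assert rois.provenance == "auto"
        for roi in rois.signal_rois:
            assert mask[int(roi.center[0]), int(roi.center[1])]

    def test_background_far_from_mask(self, straight_vessel):
        from scipy.ndimage import distance_transform_edt
        img, mask = straight_vessel
        rois = am.auto_rois(img, mask, min_background_distance=6, seed=0,
                            radius=4)
        dist = distance_transform_edt(~mask)
        for roi in rois.background_rois:
            assert dist[int(roi.center[0]), int(roi.center[1])] >= 10

    def test_deterministic_given_seed(self, straight_vessel):
        img, mask = straight_vessel
        a = am.auto_rois(img, mask, seed=5)
        b = am.auto_rois(img, mask, seed=5)
        assert a == b

    def test_oversized_distance_errors(self, straight_vessel):
        img, mask = straight_vessel
        with pytest.raises(am.ROIPlacementError):
            am.auto_rois(img, mask, min_background_distance=500)


class TestProfiles:
    def test_ramp_rows_recovered(self):
        img = np.tile(np.arange(10.0), (10, 1))
        prof = am.extract_profile(img, (4, 0), (4, 9))
        np.testing.assert_allclose(prof.intensities, np.arange(10.0))

    def test_positions_span(self):
        img = np.zeros((30, 30))
        prof = am.extract_profile(img, (5, 5), (5, 25), pixel_size_mm=0.1)
        assert len(prof.positions) == 21
        assert prof.positions[-1] == pytest.approx(2.0)

    def test_gaussian_vessel_peak_on_centerline(self):
        y, x = np.mgrid[:40, :40]
        img = np.exp(-((y - 20.3) ** 2) / (2 * 2.0 ** 2))
        prof = am.extract_profile(img, (5, 20), (35, 20))
        peak_pos = prof.positions[np.argmax(prof.intensities)]
        assert abs(peak_pos - 15.3) <= 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            am.extract_profile(np.zeros((10, 10)), (3, 3), (3, 3))


class TestFWHM:
    @pytest.mark.parametrize("sigma_mm", [0.1, 0.2, 0.5])
    def test_gaussian_closed_form(self, sigma_mm):
        x = np.arange(-3, 3, sigma_mm / 8)
        y = np.exp(-x ** 2 / (2 * sigma_mm ** 2))
        prof = am.LineProfile(x - x[0], y, pixel_size_mm=1.0)
        expected = am.GAUSSIAN_FWHM_FACTOR * sigma_mm
        assert am.fwhm(prof) == pytest.approx(expected, rel=0.02)

    def test_rectangular_pulse(self):
        x = np.arange(0, 10, 0.1)
        y = np.where((x >= 3) & (x <= 6), 1.0, 0.0)
        # allowed error is one sample spacing (0.1), plus float epsilon
        assert am.fwhm(am.LineProfile(x, y, 1.0)) == pytest.approx(
            3.0, abs=0.1 + 1e-9)

    def test_triangle_base_halved(self):
        x = np.arange(0, 8, 0.05)
        y = np.clip(1 - np.abs(x - 4) / 2, 0, None)  # base 4
        assert am.fwhm(am.LineProfile(x, y, 1.0)) == pytest.approx(2.0,
                                                                   abs=0.05)

    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-2.0, max_value=2.0))
    @settings(deadline=None, max_examples=25)
    def test_affine_intensity_invariance(self, gain, offset):
        x = np.arange(-2, 2, 0.02)
        y = np.exp(-x ** 2 / (2 * 0.3 ** 2)) + 0.1
        base = am.fwhm(am.LineProfile(x - x[0], y, 1.0))
        mapped = am.fwhm(am.LineProfile(x - x[0], gain * y + offset, 1.0))
        assert mapped == pytest.approx(base, rel=1e-6)

    def test_unresolved_peak_errors(self):
        x = np.arange(0, 5, 0.5)
        with pytest.raises(ProfileError):
            am.fwhm(am.LineProfile(x, x.copy(), 1.0))  # monotone ramp


class TestScalarMetrics:
    def test_fold_change_printed_sbrs(self):
        assert round(am.fold_change(3.32, 1.26), 1) == 2.6

    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100))
    def test_fold_change_reciprocal(self, a, b):
        assert am.fold_change(a, b) * am.fold_change(b, a) == \
            pytest.approx(1.0)

    def test_fold_change_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            am.fold_change(1.0, 0.0)

    def test_retention(self):
        assert am.retention([1.0, 0.6, 0.28]) == pytest.approx(0.28)
        assert am.retention([0.5, 0.5, 0.5]) == 1.0
        t = np.linspace(0, 10, 11)
        trace = 2.0 * np.exp(-0.3 * t)
        assert am.retention(trace) == pytest.approx(np.exp(-3.0))

    def test_hemolysis(self):
        assert am.hemolysis_percent(0.10, 0.10, 0.90) == 0.0
        assert am.hemolysis_percent(0.90, 0.10, 0.90) == 100.0
        assert am.hemolysis_percent(0.30, 0.10, 0.90) == pytest.approx(25.0)
        with pytest.raises(ValidationError):
            am.hemolysis_percent(0.3, 0.9, 0.9)


class TestStokesShift:
    @staticmethod
    def spectrum(peak_nm, lo, hi, width=30.0):
        w = np.linspace(lo, hi, 400)
        return am.SpectrumRecord(w, np.exp(-(w - peak_nm) ** 2 /
                                           (2 * width ** 2)))

    def test_icg_and_tcp_peaks(self):
        # ICG: absorption max 796 nm, emission max 854 nm -> 58 nm
        s = am.stokes_shift(self.spectrum(796, 600, 1000),
                            self.spectrum(854, 650, 1100))
        assert float(s) == pytest.approx(58.0, abs=1.1)
        # TCP: absorption max 731 nm, emission max 1081 nm -> 350 nm
        s = am.stokes_shift(self.spectrum(731, 550, 950),
                            self.spectrum(1081, 850, 1400))
        assert float(s) == pytest.approx(350.0, abs=1.5)

    def test_identical_spectra_zero(self):
        s = self.spectrum(800, 600, 1000)
        assert float(am.stokes_shift(s, s)) == 0.0

    def test_tie_breaks_to_longest_and_flags(self):
        w = np.array([700.0, 750.0, 800.0, 850.0])
        v = np.array([0.1, 1.0, 1.0, 0.1])
        rec = am.SpectrumRecord(w, v)
        peak, tied = rec.peak_wavelength()
        assert peak == 800.0 and tied
        res = am.stokes_shift(rec, rec)
        assert res.tie_broken


class TestHalfLife:
    def test_noiseless_recovery(self):
        t = np.array([0.0, 12, 24, 48, 120])
        v = am.mono_exponential(t, 1.0, 45.0)
        fit = am.fit_halflife(am.DecaySeries(t, v))
        assert not fit.diverged
        assert fit.halflife_h == pytest.approx(45.0, rel=1e-3)

    def test_noisy_recovery_simulation(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 120, 9)
        hits = 0
        for _ in range(100):
            v = am.mono_exponential(t, 1.0, 45.0) * \
                (1 + 0.05 * rng.standard_normal(t.size))
            fit = am.fit_halflife(am.DecaySeries(t, np.abs(v)))
            if abs(fit.halflife_h - 45.0) / 45.0 <= 0.10:
                hits += 1
        assert hits >= 90

    def test_constant_series_flags_divergence(self):
        t = np.linspace(0, 48, 6)
        fit = am.fit_halflife(am.DecaySeries(t, np.ones(6)))
        assert fit.diverged

    def test_validation(self):
        with pytest.raises(ValidationError):
            am.fit_halflife(am.DecaySeries(np.array([0.0, 1, 2]),
                                           np.array([1.0, 0.9, 0.8])))
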