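import numpy as np
import pytest

from nemabench.core import ProjectionImage
from nemabench.nema_planar import (
    AnalysisError,
    CountRateAnalysis,
    ProfileAnalysis,
    SensitivityMeasurement,
    count_rate_fit,
    decay_corrected_rate,
    energy_resolution,
    flood_uniformity,
    intrinsic_resolution_linearity,
    mwsr,
    nema_fwhm,
    sensitivity_fit,
    system_resolution,
)
from nemabench.scenarios import simulate_flood_image, simulate_slit_mask_image
from nemabench.synthetic_data import ISOTOPES


class _Point:
    def __init__(self, time, ocr):
        self.time, self.ocr = time, ocr


class TestNemaFwhm:
    def test_three_point_triangle(self):
        pa = nema_fwhm([0.0, 1.0, 0.0], pitch=1.0)
        assert pa.fwhm == pytest.approx(1.0)
        assert pa.peak_amplitude == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma_px", [10.0, 30.0, 80.0])
    def test_gaussian_accuracy_below_one_percent(self, sigma_px):
        x = np.arange(0, max(20 * sigma_px, 200))
        y = np.exp(-0.5 * ((x - x.mean()) / sigma_px) ** 2)
        pa = nema_fwhm(y, pitch=1.0)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma_px
        assert pa.fwhm == pytest.approx(expected, rel=0.01)
        assert pa.fwtm / pa.fwhm == pytest.approx(1.8226, abs=0.01)

    def test_gaussian_one_mm_sigma_at_tenth_mm_pitch(self):
        x = np.arange(-10, 10, 0.1)
        y = np.exp(-0.5 * x**2)
        pa = nema_fwhm(y, pitch=0.1)
        assert pa.fwhm == pytest.approx(2.355, abs=0.005)

    def test_tie_breaks_toward_center(self):
        y = np.array([0, 5, 1, 1, 5, 1, 5, 1, 0], dtype=float)
        pa = nema_fwhm(y, pitch=1.0)
        assert abs(pa.peak_position - 4.0) <= 1.0

    def test_profile_not_falling_below_level_is_error(self):
        with pytest.raises(AnalysisError):
            nema_fwhm([5.0, 5.1, 5.0], pitch=1.0)

    def test_photopeak_energy_resolution(self):
        # FWHM 20.65 keV at 140.5 keV -> 14.7%
        e = np.arange(100, 180, 0.6)
        sigma = 20.65 / (2 * np.sqrt(2 * np.log(2)))
        y = np.exp(-0.5 * ((e - 140.5) / sigma) ** 2)
        res = energy_resolution(y, 0.6, first_bin_center=e[0])
        assert res["energy_resolution_pct"] == pytest.approx(14.7, abs=0.05)


class TestIntrinsicResolutionLinearity:
    def test_undistorted_slits_have_zero_linearity(self):
        img = simulate_slit_mask_image(n_events=400_000, seed=0)
        res = intrinsic_resolution_linearity(img)
        assert res.differential_linearity["UFOV"] < 0.08
        assert res.absolute_linearity["UFOV"] < 0.25
        assert res.fwhm_mean["UFOV"] == pytest.approx(1.0, abs=0.25)

    def test_known_sinusoidal_warp_recovered(self):
        img = simulate_slit_mask_image(n_events=600_000, seed=1,
                                       warp_amplitude=0.4)
        res = intrinsic_resolution_linearity(img)
        assert res.absolute_linearity["UFOV"] == pytest.approx(0.4, abs=0.12)

    def test_calibration_factor_matches_pitch(self):
        img = simulate_slit_mask_image(n_events=400_000, seed=2, pitch=0.099)
        res = intrinsic_resolution_linearity(img)
        assert res.calibration_mm_per_pixel == pytest.approx(0.099, abs=0.002)

    def test_too_few_slits_is_error(self):
        img = ProjectionImage(np.zeros((1020, 1020)), pixel_pitch=0.1,
                              origin=(-51, -51))
        with pytest.raises(AnalysisError):
            intrinsic_resolution_linearity(img)


class TestFloodUniformity:
    def _flat(self, value=100.0):
        return ProjectionImage(np.full((102, 102), value), pixel_pitch=1.0,
                               origin=(-51, -51))

    def test_flat_image_is_perfectly_uniform(self):
        res = flood_uniformity(self._flat())
        assert res.integral["UFOV"] == 0.0
        assert res.row_differential["CFOV"] == 0.0

    def test_integral_formula(self):
        # post-smoothing max 103 / min 97 -> 3.0%
        assert (103 - 97) / (103 + 97) * 100 == pytest.approx(3.0)
        img = self._flat()
        img.counts[51, 51] = 120.0  # bump the centre pixel
        res = flood_uniformity(img)
        sm_max = res.pixel_max["UFOV"]
        sm_min = res.pixel_min["UFOV"]
        expected = (sm_max - sm_min) / (sm_max + sm_min) * 100
        assert res.integral["UFOV"] == pytest.approx(expected)
        assert res.integral["UFOV"] > 0

    def test_differential_not_above_integral(self):
        img = simulate_flood_image(total_counts=2e6, seed=3)
        res = flood_uniformity(img)
        for region in ("UFOV", "CFOV"):
            assert res.row_differential[region] <= res.integral[region] + 1e-9
            assert res.column_differential[region] <= res.integral[region] + 1e-9

    def test_smoothing_reduces_poisson_uniformity(self, rng):
        counts = rng.poisson(500.0, (102, 102)).astype(float)
        img = ProjectionImage(counts, pixel_pitch=1.0, origin=(-51, -51))
        res = flood_uniformity(img)
        mask = img.mask_for("UFOV")
        raw = counts[mask]
        raw_iu = (raw.max() - raw.min()) / (raw.max() + raw.min()) * 100
        assert res.integral["UFOV"] < raw_iu


class TestMwsr:
    def _psf(self, cx, cy):
        x = np.arange(-5, 5, 0.1)
        xx, yy = np.meshgrid(x, x)
        c = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.36**2))
        return ProjectionImage(c, pixel_pitch=0.1, origin=(-5, -5))

    def test_identical_psfs_have_zero_displacement(self):
        imgs = {(0, 0): {"a": self._psf(0, 0), "b": self._psf(0, 0)}}
        res = mwsr(imgs)
        assert res.max_axial_displacement == pytest.approx(0.0, abs=1e-9)
        assert res.mean_euclidean_distance == pytest.approx(0.0, abs=1e-9)

    def test_single_window_shift_detected(self):
        imgs = {(0, 0): {"a": self._psf(0.2, 0.0), "b": self._psf(0.0, 0.0)}}
        res = mwsr(imgs)
        assert res.max_transaxial_displacement == pytest.approx(0.2, abs=0.02)

    def test_three_window_mean_distance(self):
        # centroids at -0.1, 0, +0.1 mm -> mean distance 0.0667 mm
        imgs = {(0, 0): {"a": self._psf(-0.1, 0), "b": self._psf(0, 0),
                         "c": self._psf(0.1, 0)}}
        res = mwsr(imgs)
        assert res.mean_euclidean_distance == pytest.approx(0.0667, abs=0.005)


class TestCountRateFit:
    def test_noise_free_recovery_is_exact(self):
        lam = ISOTOPES["Tc99m"].decay_constant
        tau, icr0 = 23.9e-6, 1.2e5
        t = np.arange(0, 40 * 3600.0, 3600.0)
        icr = icr0 * np.exp(-lam * t)
        pts = [_Point(ti, ic * np.exp(-ic * tau)) for ti, ic in zip(t, icr)]
        fit = count_rate_fit(pts, lam)
        assert fit.tau == pytest.approx(tau, rel=1e-10)
        assert fit.icr0 == pytest.approx(icr0, rel=1e-10)

    def test_peak_and_loss_rates_for_printed_deadtime(self):
        fit = CountRateAnalysis(tau=23.9e-6, icr0=1e5,
                                max_ocr=1 / (np.e * 23.9e-6),
                                loss20_ocr=0.8 * np.log(1.25) / 23.9e-6,
                                n_points=40, slope=0.0, intercept=0.0)
        assert round(fit.max_ocr, -2) == 15_400
        assert fit.loss20_ocr == pytest.approx(7469, abs=1.0)

    def test_nonpositive_ocr_dropped_with_warning(self):
        lam = ISOTOPES["Tc99m"].decay_constant
        tau = 20e-6

        def ocr(icr):
            return icr * np.exp(-icr * tau)

        pts = [_Point(i * 3600.0, ocr(1e4 * np.exp(-lam * i * 3600.0)))
               for i in range(8)]
        pts.append(_Point(9 * 3600.0, 0.0))
        with pytest.warns(UserWarning):
            fit = count_rate_fit(pts, lam)
        assert fit.n_points == 8


class TestSystemResolution:
    def _profiles(self, fwhms, distances):
        return {d: ProfileAnalysis(fwhm=f, fwtm=1.82 * f, peak_position=0.0,
                                   peak_amplitude=1.0)
                for d, f in zip(distances, fwhms)}

    def test_unity_magnification_distance(self):
        # source-to-aperture equal to aperture-to-crystal: M = 1
        prof = self._profiles([2.0] * 5, [21.75, 25, 50, 75, 100])
        fit = system_resolution(prof)
        assert fit.fwhm_object[0] == pytest.approx(2.0)

    def test_cor_magnification_correction(self):
        prof = self._profiles([2.0] * 5, [23.0, 25, 50, 75, 100])
        fit = system_resolution(prof)
        assert fit.fwhm_object[0] == pytest.approx(2.0 * 28.0 / 26.75)

    def test_perfectly_linear_data_gives_unit_r_squared(self):
        d = np.array([0.4, 25, 50, 75, 100])
        prof = self._profiles(1.12 + 0.0424 * d, d)
        # detector-space widths constructed in object space: undo the factor
        for dist in d:
            prof[dist].fwhm *= 26.75 / (dist + 5.0)
            prof[dist].fwtm = max(prof[dist].fwtm, prof[dist].fwhm)
        fit = system_resolution(prof)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.fwhm_at_cor == pytest.approx(1.12 + 0.0424 * 23.0, rel=1e-9)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            system_resolution(self._profiles([1.0], [-2.0]))


class TestSensitivity:
    def test_decay_corrected_rate_limits(self):
        lam = ISOTOPES["Tc99m"].decay_constant
        m = SensitivityMeasurement(counts=1e4, start_time=0.0, acq_time=100.0,
                                   distance=23.0, decay_constant=1e-15)
        assert decay_corrected_rate(m) == pytest.approx(1e4 / 100.0)
        half = ISOTOPES["Tc99m"].half_life
        m2 = SensitivityMeasurement(counts=1e6, start_time=0.0, acq_time=half,
                                    distance=23.0, decay_constant=lam)
        assert decay_corrected_rate(m2) == pytest.approx(lam * 1e6 / 0.5)
        m3 = SensitivityMeasurement(counts=0.0, start_time=10.0, acq_time=5.0,
                                    distance=23.0, decay_constant=lam)
        assert decay_corrected_rate(m3) == 0.0

    def test_invalid_acquisition_time(self):
        m = SensitivityMeasurement(counts=1.0, start_time=0.0, acq_time=0.0,
                                   distance=10.0, decay_constant=1e-5)
        with pytest.raises(ValueError):
            decay_corrected_rate(m)

    def test_exact_exponential_recovered(self):
        # generating curve printed for the 1.0 mm pinhole simulation
        c0, c1, c2 = 4.33, 148.0, 0.0563
        lam = 1e-9  # effectively no decay: counts encode the rates directly
        ms = [SensitivityMeasurement(counts=(c0 + c1 * np.exp(-c2 * d)) * 100.0,
                                     start_time=0.0, acq_time=100.0, distance=d,
                                     decay_constant=lam)
              for d in (10, 20, 28, 50, 100)]
        fit = sensitivity_fit(ms, a_cal=1.0)
        assert fit.c0 == pytest.approx(c0, abs=1e-6)
        assert fit.c1 == pytest.approx(c1, abs=1e-5)
        assert fit.c2 == pytest.approx(c2, abs=1e-8)
        assert fit.s_tot(23.0) == pytest.approx(44.9, abs=0.05)

    def test_flat_data_flagged_degenerate(self):
        ms = [SensitivityMeasurement(counts=500.0, start_time=0.0,
                                     acq_time=100.0, distance=d,
                                     decay_constant=1e-9)
              for d in (10, 20, 28, 50, 100)]
        with pytest.warns(UserWarning):
            fit = sensitivity_fit(ms, a_cal=1.0)
        assert fit.degenerate

    def test_unbiased_on_poisson_noise(self, rng):
        c0, c1, c2 = 4.33, 148.0, 0.0563
        resid = []
        for _ in range(20):
            ms = [SensitivityMeasurement(
                counts=rng.poisson((c0 + c1 * np.exp(-c2 * d)) * 100.0),
                start_time=0.0, acq_time=100.0, distance=d, decay_constant=1e-9)
                for d in (10, 20, 28, 50, 100)]
            fit = sensitivity_fit(ms, a_cal=1.0)
            resid.append(fit.s_tot(23.0) - (c0 + c1 * np.exp(-c2 * 23.0)))
        mean = np.mean(resid)
        sem = np.std(resid) / np.sqrt(len(resid))
        assert abs(mean) < 4 * sem + 0.05
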