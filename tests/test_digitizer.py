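import numpy as np
import pytest

from nemabench.core import EventList, bin_spectrum
from nemabench.digitizer import (
    DigitizerConfig,
    PileupStats,
    apply_chain,
    calibrate_parameter,
    deadtime_throughput,
    measure_pileup_stats,
    tmin_from_peaks,
)
from nemabench.nema_planar import nema_fwhm


def _stream(times, energies=None, x=None, y=None):
    n = len(times)
    energies = np.full(n, 140.511) if energies is None else np.asarray(energies, float)
    x = np.zeros(n) if x is None else np.asarray(x, float)
    y = np.zeros(n) if y is None else np.asarray(y, float)
    return EventList(np.asarray(times, float), x, y, energies, np.ones(n),
                     duration=float(max(times) + 1) if n else 1.0)


class TestChain:
    def test_identity_when_all_losses_disabled(self, identity_digitizer, rng):
        n = 500
        ev = _stream(np.sort(rng.uniform(0, 10, n)),
                     rng.uniform(100, 200, n), rng.normal(size=n),
                     rng.normal(size=n))
        out = apply_chain(ev, identity_digitizer, seed=0)
        np.testing.assert_array_equal(out.t, ev.t)
        np.testing.assert_array_equal(out.x, ev.x)
        np.testing.assert_array_equal(out.energy, ev.energy)

    def test_unsorted_input_rejected(self, identity_digitizer):
        ev = _stream([0.0, 1.0])
        ev.t = np.array([1.0, 0.0])  # deliberately corrupt ordering
        with pytest.raises(ValueError):
            apply_chain(ev, identity_digitizer, seed=0)

    def test_pileup_merges_summed_energy_midpoint_position(self):
        cfg = DigitizerConfig(energy_resolution_ref=0.0, spatial_blur_fwhm=0.0,
                              pileup_tmin=1e-6, dead_time=0.0)
        ev = _stream([0.0, 5e-7], x=[0.0, 1.0])
        out = apply_chain(ev, cfg, seed=0)
        assert len(out) == 1
        assert out.energy[0] == pytest.approx(2 * 140.511)
        assert out.x[0] == pytest.approx(0.5)  # energy-weighted centroid

    def test_paralyzable_deadtime_logic(self):
        tau = 10e-6
        cfg = DigitizerConfig(energy_resolution_ref=0.0, spatial_blur_fwhm=0.0,
                              pileup_tmin=0.0, dead_time=tau)
        ev = _stream([0.0, tau / 2, 2 * tau], x=[1.0, 2.0, 3.0])
        out = apply_chain(ev, cfg, seed=0)
        # arrivals 1 and 3 survive: the middle arrival is within tau of the
        # first, and itself extends the dead interval
        np.testing.assert_allclose(out.x, [1.0, 3.0])

    def test_output_never_exceeds_input(self, rng):
        cfg = DigitizerConfig(pileup_tmin=2e-6, dead_time=10e-6, efficiency=0.9)
        n = 2000
        ev = _stream(np.sort(rng.uniform(0, 0.05, n)))
        out = apply_chain(ev, cfg, seed=0)
        assert len(out) <= n

    def test_energy_blur_fwhm_at_reference(self, rng):
        cfg = DigitizerConfig(energy_resolution_ref=0.10, spatial_blur_fwhm=0.0,
                              pileup_tmin=0.0, dead_time=0.0)
        n = 200_000
        ev = _stream(np.sort(rng.uniform(0, 100, n)))
        out = apply_chain(ev, cfg, seed=1)
        counts, _ = bin_spectrum(out, 0.3)
        fwhm = nema_fwhm(counts, 0.3).fwhm
        assert fwhm == pytest.approx(0.10 * 140.511, rel=0.02)

    def test_pileup_spectrum_harmonics_and_rate_dependence(self, rng):
        cfg = DigitizerConfig(energy_resolution_ref=0.0, spatial_blur_fwhm=0.0,
                              pileup_tmin=4e-6, dead_time=0.0)
        ratios = []
        for rate in (5e3, 2e4):
            n = int(rate * 20)
            ev = _stream(np.sort(rng.uniform(0, 20.0, n)))
            out = apply_chain(ev, cfg, seed=2)
            e0 = 140.511
            p0 = np.sum(np.abs(out.energy - e0) < 10)
            p1 = np.sum(np.abs(out.energy - 2 * e0) < 10)
            assert p0 > 0 and p1 > 0
            # merged energies sit at multiples of the line energy
            k = out.energy / e0
            assert np.allclose(k, np.round(k), atol=1e-9)
            ratios.append(p1 / p0)
        assert ratios[1] > ratios[0]


class TestPileupTiming:
    def test_limit_cases(self):
        assert tmin_from_peaks(PileupStats(p0=100, p1=0, r_true=1e4)) == 0.0
        val = tmin_from_peaks(PileupStats(p0=7, p1=7, r_true=1e4))
        assert val == pytest.approx(1.0 / (3 * 1e4))

    def test_direct_substitution(self):
        # P0=9000, P1=500, R_T=10 kcps -> 5 us
        stats = PileupStats(p0=9000, p1=500, r_true=1e4)
        assert tmin_from_peaks(stats) == pytest.approx(5.0e-6)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            PileupStats(p0=1, p1=1, r_true=0.0)

    def test_recovers_configured_window_at_low_rate(self, rng):
        t_min = 3e-6
        rate = 3e3  # small pile-up regime where the estimator is valid
        cfg = DigitizerConfig(energy_resolution_ref=0.0, spatial_blur_fwhm=0.0,
                              pileup_tmin=t_min, dead_time=0.0)
        n = int(rate * 200)
        ev = _stream(np.sort(rng.uniform(0, 200.0, n)))
        out = apply_chain(ev, cfg, seed=3)
        stats = measure_pileup_stats(out, 140.511, r_true=rate)
        assert tmin_from_peaks(stats) == pytest.approx(t_min, rel=0.1)


class TestDeadtimeThroughput:
    def test_zero_deadtime_is_identity(self):
        assert deadtime_throughput(1234.5, 0.0) == pytest.approx(1234.5)

    def test_curve_maximum_at_inverse_tau(self):
        tau = 23.9e-6
        icr = np.linspace(1e3, 2e5, 2000)
        ocr = deadtime_throughput(icr, tau)
        assert ocr.max() == pytest.approx(1.0 / (np.e * tau), rel=1e-4)
        assert icr[np.argmax(ocr)] == pytest.approx(1.0 / tau, rel=1e-2)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            deadtime_throughput(100.0, -1e-6)

    def test_event_thinning_matches_formula(self, rng):
        tau = 20e-6
        icr = 3e4
        duration = 40.0
        n = rng.poisson(icr * duration)
        cfg = DigitizerConfig(energy_resolution_ref=0.0, spatial_blur_fwhm=0.0,
                              pileup_tmin=0.0, dead_time=tau)
        ev = _stream(np.sort(rng.uniform(0, duration, n)))
        out = apply_chain(ev, cfg, seed=4)
        expected = deadtime_throughput(icr, tau) * duration
        assert abs(len(out) - expected) < 3 * np.sqrt(expected)


class TestCalibration:
    def test_quadratic_observable_inverted_exactly(self):
        value = calibrate_parameter("p", lambda p: p**2, 4.0,
                                    grid=[0.5, 1.5, 2.5, 3.5, 4.5])
        assert value == pytest.approx(2.0, abs=1e-6)

    def test_linear_observable_inverted_exactly(self):
        value = calibrate_parameter("p", lambda p: 3 * p + 1, 7.0,
                                    grid=[0, 1, 2, 3, 4])
        assert value == pytest.approx(2.0, abs=1e-9)

    def test_non_bracketing_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_parameter("p", lambda p: p, 10.0, grid=[0, 1, 2, 3])

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_parameter("p", lambda p: p, 1.0, grid=[0, 1, 2])
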