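"""100% lines, RMS noise statistic, SNR, duration scaling, noise injection."""

import numpy as np
import pytest

from phantomnir import noise, spectra


def _sb(grid, vals, t=0.0):
    return spectra.SingleBeamSpectrum(grid, np.asarray(vals, float), timestamp_s=t)


@pytest.fixture(scope="module")
def grid16():
    return spectra.WavelengthGrid(np.linspace(1400.0, 2400.0, 16))


class TestHundredPercentLine:
    def test_identical_scans_give_zeros(self, grid16):
        s = _sb(grid16, np.full(16, 123.0))
        line = noise.hundred_percent_line(s, s)
        assert np.allclose(line.values, 0.0)

    def test_decade_ratio_gives_one_au(self, grid16):
        s1 = _sb(grid16, np.full(16, 100.0))
        s2 = _sb(grid16, np.full(16, 1000.0))
        assert np.allclose(noise.hundred_percent_line(s1, s2).values, 1.0)

    def test_antisymmetry(self, grid16):
        rng = np.random.default_rng(0)
        s1 = _sb(grid16, rng.uniform(50, 150, 16))
        s2 = _sb(grid16, rng.uniform(50, 150, 16))
        a = noise.hundred_percent_line(s1, s2).values
        b = noise.hundred_percent_line(s2, s1).values
        assert np.allclose(a, -b)

    def test_grid_mismatch_rejected(self, grid16, grid112):
        with pytest.raises(ValueError):
            noise.hundred_percent_line(_sb(grid16, np.full(16, 1.0)),
                                       _sb(grid112, np.full(112, 1.0)))


class TestDetrend:
    def test_quadratic_annihilation(self, grid16):
        wl = grid16.wavelengths
        quad = 1e-3 + 2e-6 * wl + 3e-9 * wl**2
        line = noise.HundredPercentLine(grid16, quad)
        out = noise.detrend(line, k=2)
        assert np.abs(out.residuals).max() < 1e-12

    def test_constant_offset_removed(self, grid16):
        out = noise.detrend(noise.HundredPercentLine(grid16, np.full(16, 0.5)), k=2)
        assert np.abs(out.residuals).max() < 1e-12

    def test_residuals_recover_component_orthogonal_to_basis(self, grid16):
        """A residual built orthogonal to the quadratic basis passes through."""
        wl = grid16.wavelengths
        x = 2 * (wl - wl.min()) / (wl.max() - wl.min()) - 1
        basis = np.vander(x, 3, increasing=True)  # 1, x, x^2
        q, _ = np.linalg.qr(basis)
        rng = np.random.default_rng(3)
        r = rng.normal(size=16)
        r -= q @ (q.T @ r)  # explicit projection off the fitted basis
        quad = 0.2 - 0.1 * x + 0.05 * x**2
        out = noise.detrend(noise.HundredPercentLine(grid16, quad + r), k=2)
        assert np.allclose(out.residuals, r, atol=1e-10)

    def test_rms_invariant_under_quadratic_absorbance_shift(self, grid16):
        """Adding a quadratic to both ratioed spectra leaves the RMS unchanged."""
        rng = np.random.default_rng(4)
        wl = grid16.wavelengths
        a1 = 0.5 + rng.normal(0, 1e-4, 16)
        a2 = 0.5 + rng.normal(0, 1e-4, 16)
        quad = 1e-2 + 1e-5 * wl + 1e-8 * wl**2
        def line_rms(x1, x2):
            s1 = _sb(grid16, 10.0 ** (-x1))
            s2 = _sb(grid16, 10.0 ** (-x2))
            return noise.rms_noise(noise.detrend(noise.hundred_percent_line(s1, s2)))
        assert line_rms(a1, a2) == pytest.approx(line_rms(a1 + quad, a2 + quad), rel=1e-9)


class TestRMSNoise:
    def test_zero_residuals(self, grid16):
        line = noise.detrend(noise.HundredPercentLine(grid16, np.zeros(16)), k=2)
        assert noise.rms_noise(line) == 0.0

    def test_hand_value_alternating_residuals(self):
        """Residuals +-1 mAU over N=4, k=2: sqrt(4/(4-1-2)) mAU = 2000 uAU."""
        grid = spectra.WavelengthGrid(np.array([1400.0, 1500.0, 1600.0, 1700.0]))
        line = noise.HundredPercentLine(grid, np.zeros(4), k=2,
                                        residuals=np.array([1, -1, 1, -1]) * 1e-3)
        assert noise.rms_noise(line, k=2) == pytest.approx(2000.0)

    def test_too_few_wavelengths_rejected(self):
        grid = spectra.WavelengthGrid(np.array([1400.0, 1500.0, 1600.0]))
        line = noise.HundredPercentLine(grid, np.zeros(3), k=2, residuals=np.zeros(3))
        with pytest.raises(ValueError):
            noise.rms_noise(line, k=2)

    def test_undetrended_line_rejected(self, grid16):
        with pytest.raises(ValueError):
            noise.rms_noise(noise.HundredPercentLine(grid16, np.zeros(16)))


class TestSNR:
    @pytest.mark.parametrize("rms,expected_3sf", [(15.0, 28900), (33.8, 12800)])
    def test_reported_snr_values(self, rms, expected_3sf):
        val = noise.snr(rms)
        # round to 3 significant figures
        from math import floor, log10
        k = 3 - 1 - floor(log10(abs(val)))
        assert round(val, k) == expected_3sf

    def test_exact_inverse_relation(self):
        rms_au = 1.0 / 2.303
        assert noise.snr(rms_au * 1e6) == pytest.approx(1.0)
        # snr(rms) * 2.303 * rms(AU) = 1 identically
        for rms in (3.0, 15.0, 327.8):
            assert noise.snr(rms) * 2.303 * rms * 1e-6 == pytest.approx(1.0)


class TestDurationScaling:
    def test_identity_and_quarter(self):
        assert noise.scale_rms_to_duration(100.0, 1) == 100.0
        assert noise.scale_rms_to_duration(100.0, 4) == 50.0

    def test_fractional_scan_count_used_as_is(self):
        """327.8 uAU scaled by 8.33 scans/s x 60 s = 499.8 scans -> 14.66 uAU."""
        out = noise.scale_rms_to_duration(327.8, 8.33 * 60.0)
        assert out == pytest.approx(14.66, abs=0.005)


class TestBenchmarkDataset:
    def test_identical_scans_give_zero_median(self, grid16):
        scans = [_sb(grid16, np.full(16, 50.0), t=i * 0.1) for i in range(4)]
        series = spectra.SpectralTimeSeries(scans, 10.0, phantom_id="P01")
        res = noise.benchmark_dataset({"P01": series})
        assert res.median == 0.0

    def test_white_noise_median_is_sqrt2_sigma(self, grid112, lib):
        """Lines from scans with absorbance noise sigma have RMS ~ sqrt(2)*sigma."""
        sigma = 400.0
        ts = spectra.simulate_time_series({}, grid112, lib, 60.0, 8.33,
                                          noise_rms_uau=sigma, seed=21)
        res = noise.benchmark_dataset([ts])
        assert res.median == pytest.approx(np.sqrt(2) * sigma, rel=0.05)

    def test_deterministic_given_seeded_input(self, grid112, lib):
        ts = spectra.simulate_time_series({}, grid112, lib, 5.0, 8.33,
                                          noise_rms_uau=300.0, seed=2)
        r1 = noise.benchmark_dataset([ts])
        r2 = noise.benchmark_dataset([ts])
        assert np.array_equal(r1.all_rms, r2.all_rms)

    def test_two_to_one_sigma_gives_two_to_one_medians(self, grid112, lib):
        medians = []
        for sig, seed in ((300.0, 31), (600.0, 32)):
            ts = spectra.simulate_time_series({}, grid112, lib, 40.0, 8.33,
                                              noise_rms_uau=sig, seed=seed)
            medians.append(noise.benchmark_dataset([ts]).median)
        assert medians[1] / medians[0] == pytest.approx(2.0, rel=0.1)


@pytest.fixture(scope="module")
def baseline_series(grid112, lib):
    return {
        f"P{i}": spectra.simulate_time_series(
            {}, grid112, lib, 12.0, 8.33, noise_rms_uau=327.8 / np.sqrt(2),
            seed=100 + i)
        for i in range(4)
    }


class TestInjectionCalibration:
    def test_target_equal_baseline_gives_zero_sigma(self, baseline_series):
        base = noise.benchmark_dataset(baseline_series).median
        sigma, achieved = noise.calibrate_injection_noise(baseline_series, base, seed=0)
        assert sigma == 0.0 and achieved == base

    def test_calibration_hits_target_median(self, baseline_series):
        sigma, achieved = noise.calibrate_injection_noise(
            baseline_series, 667.2, tol_uau=2.0, seed=0)
        assert achieved == pytest.approx(667.2, rel=0.02)
        assert sigma > 0

    def test_median_monotone_in_sigma(self, baseline_series):
        rng_seed = 7
        meds = []
        for sigma in (0.0, 2e-4, 4e-4, 8e-4):
            rng = np.random.default_rng(rng_seed)
            noisy = {p: noise.add_absorbance_noise(s, sigma, rng)
                     for p, s in baseline_series.items()}
            meds.append(noise.benchmark_dataset(noisy).median)
        assert all(b > a for a, b in zip(meds, meds[1:]))

    def test_target_below_baseline_rejected(self, baseline_series):
        with pytest.raises(ValueError, match="below"):
            noise.calibrate_injection_noise(baseline_series, 10.0, seed=0)
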