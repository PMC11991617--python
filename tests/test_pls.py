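"""SIMPLS regression, cross-validation, grid search, randomization control."""

import numpy as np
import pytest

from phantomnir import pls, spectra
from phantomnir.preprocess import AbsorbanceSpectrum


def _toy_dataset(n=20, p=15, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    grid = spectra.WavelengthGrid(np.linspace(1400.0, 2400.0, p))
    X = rng.normal(size=(n, p))
    y = X[:, 2] * 3.0 + rng.normal(scale=0.1, size=n) if signal else rng.normal(size=n)
    return pls.CalibrationDataset(X, y, [f"p{i:02d}" for i in range(n)], grid)


class TestSimpls:
    def test_matches_nipals_cross_check(self):
        """SIMPLS predictions agree with the independent NIPALS implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        ds = _toy_dataset()
        for a in (1, 2, 5):
            model = pls.fit_pls(ds, a)
            ours = pls.predict(model, ds.X)
            ref = sklearn.PLSRegression(n_components=a, scale=False)
            theirs = ref.fit(ds.X, ds.y.reshape(-1, 1)).predict(ds.X).ravel()
            assert np.allclose(ours, theirs, atol=1e-10)

    def test_maximal_factors_equal_least_squares_oracle(self):
        """With full factors, PLS spans the data and equals the pseudoinverse fit."""
        rng = np.random.default_rng(1)
        grid = spectra.WavelengthGrid(np.linspace(1400.0, 2400.0, 5))
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)
        ds = pls.CalibrationDataset(X, y, [f"q{i}" for i in range(6)], grid)
        model = pls.fit_pls(ds, 5)
        Xc = X - X.mean(axis=0)
        b = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.allclose(pls.predict(model, X), y.mean() + Xc @ b, atol=1e-8)

    def test_single_component_beer_lambert_is_exact(self, grid112, lib):
        """Noiseless spectra = eps(lambda)*c recovered exactly with 1 factor."""
        eps = lib.absorptivity("glucose", grid112.wavelengths)
        conc = np.linspace(0.0, 500.0, 10)
        X = np.outer(conc, eps)
        ds = pls.CalibrationDataset(X, conc, [f"c{i}" for i in range(10)], grid112)
        model = pls.fit_pls(ds, 1)
        assert np.allclose(pls.predict(model, X), conc, atol=1e-8)

    def test_column_permutation_invariance(self):
        ds = _toy_dataset()
        perm = np.random.default_rng(2).permutation(ds.X.shape[1])
        ds_perm = pls.CalibrationDataset(ds.X[:, perm], ds.y, ds.phantom_ids, ds.grid)
        p1 = pls.predict(pls.fit_pls(ds, 3), ds.X)
        p2 = pls.predict(pls.fit_pls(ds_perm, 3), ds.X[:, perm])
        assert np.allclose(p1, p2, atol=1e-10)

    def test_rank_deficiency_reports_attainable_maximum(self):
        grid = spectra.WavelengthGrid(np.linspace(1400.0, 2400.0, 6))
        X = np.outer(np.arange(8.0), np.ones(6))  # rank 1
        y = np.arange(8.0)
        ds = pls.CalibrationDataset(X, y, [f"r{i}" for i in range(8)], grid)
        with pytest.raises(np.linalg.LinAlgError, match="1 PLS factor"):
            pls.fit_pls(ds, 4)


class TestPredict:
    def test_mean_spectrum_maps_to_mean_label(self):
        ds = _toy_dataset()
        model = pls.fit_pls(ds, 3)
        assert pls.predict(model, ds.X.mean(axis=0)) == pytest.approx(ds.y.mean())

    def test_affine_linearity(self):
        ds = _toy_dataset()
        model = pls.fit_pls(ds, 4)
        s1, s2, a = ds.X[0], ds.X[1], 0.3
        lhs = pls.predict(model, a * s1 + (1 - a) * s2)
        rhs = a * pls.predict(model, s1) + (1 - a) * pls.predict(model, s2)
        assert lhs == pytest.approx(rhs)

    def test_accepts_absorbance_spectrum(self, grid112, lib):
        eps = lib.absorptivity("glucose", grid112.wavelengths)
        conc = np.linspace(0, 500, 8)
        X = np.outer(conc, eps)
        ds = pls.CalibrationDataset(X, conc, [f"c{i}" for i in range(8)], grid112)
        model = pls.fit_pls(ds, 1)
        spec = AbsorbanceSpectrum(grid112, X[3])
        assert pls.predict(model, spec) == pytest.approx(conc[3], abs=1e-6)


class TestSecv:
    def test_hand_value(self):
        assert pls.secv([0.0, 100.0], [10.0, 90.0]) == pytest.approx(10.0)

    def test_perfect_predictions(self):
        assert pls.secv([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_pair_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        yh = y + rng.normal(size=12)
        perm = rng.permutation(12)
        assert pls.secv(y, yh) == pytest.approx(pls.secv(y[perm], yh[perm]))


class TestLopoCV:
    def test_one_prediction_per_phantom(self):
        ds = _toy_dataset(n=12)
        cv = pls.lopo_cv(ds, n_factors=3)
        assert len(cv.predicted) == 12

    def test_noiseless_one_component_secv_near_zero(self, grid112, lib):
        eps = lib.absorptivity("glucose", grid112.wavelengths)
        conc = np.linspace(0.0, 500.0, 10)
        X = np.outer(conc, eps)
        ds = pls.CalibrationDataset(X, conc, [f"c{i}" for i in range(10)], grid112)
        assert pls.lopo_cv(ds, n_factors=1).secv < 1e-6

    def test_matches_naive_refit_loop(self):
        """No state leaks between folds: identical to a from-scratch loop."""
        ds = _toy_dataset(n=14, p=9)
        cv = pls.lopo_cv(ds, n_factors=3)
        naive = []
        for i in range(14):
            rows = [j for j in range(14) if j != i]
            sub = pls.CalibrationDataset(ds.X[rows], ds.y[rows],
                                         [ds.phantom_ids[j] for j in rows], ds.grid)
            naive.append(pls.predict(pls.fit_pls(sub, 3), ds.X[i]))
        assert np.allclose(cv.predicted, naive, atol=1e-12)
        assert cv.secv == pytest.approx(pls.secv(ds.y, naive))

    def test_curve_consistent_with_fixed_factor_cv(self):
        ds = _toy_dataset(n=15, p=10)
        factors, curve = pls.lopo_cv_curve(ds, max_factors=5)
        for a in (1, 3, 5):
            assert curve[a - 1] == pytest.approx(pls.lopo_cv(ds, n_factors=a).secv)


@pytest.fixture(scope="module")
def banded_dataset(grid112):
    """Glucose signal confined to the 2050-2350 nm combination window."""
    rng = np.random.default_rng(8)
    wl = grid112.wavelengths
    eps = 2e-7 * np.exp(-0.5 * ((wl - 2200.0) / 60.0) ** 2)
    eps[(wl < 2050) | (wl > 2350)] = 0.0
    conc = np.tile(np.linspace(0, 500, 7), 7)
    X = np.outer(conc, eps) + rng.normal(0, 2e-6, size=(49, 112))
    return pls.CalibrationDataset(X, conc, [f"b{i:02d}" for i in range(49)], grid112)


class TestGridSearch:
    def test_optimum_window_overlaps_signal_band(self, banded_dataset):
        gs = pls.grid_search(banded_dataset, max_factors=6)
        lo, hi = gs.best_window
        assert lo < 2350.0 and hi > 2050.0

    def test_optimum_attains_surface_minimum(self, banded_dataset):
        gs = pls.grid_search(banded_dataset, max_factors=6)
        surface_min = min(r["secv_mgdl"] for r in gs.records)
        assert gs.best_secv == pytest.approx(surface_min)
        # tie-break: no record strictly better under (secv, factors, width, start)
        best_key = (gs.best_secv, gs.best_n_factors,
                    gs.best_window[1] - gs.best_window[0], gs.best_window[0])
        for r in gs.records:
            key = (r["secv_mgdl"], r["n_factors"],
                   r["end_nm"] - r["start_nm"], r["start_nm"])
            assert key >= best_key

    def test_secv_vs_factor_curve_available(self, banded_dataset):
        gs = pls.grid_search(banded_dataset, max_factors=6)
        assert gs.secv_vs_factors is not None and len(gs.secv_vs_factors) == 6

    def test_narrow_span_rejected(self):
        grid = spectra.WavelengthGrid(np.linspace(2000.0, 2030.0, 5))
        ds = pls.CalibrationDataset(np.random.default_rng(0).normal(size=(8, 5)),
                                    np.arange(8.0), [f"x{i}" for i in range(8)], grid)
        with pytest.raises(ValueError):
            pls.grid_search(ds)


class TestDiagnostics:
    def test_perfect_predictions(self):
        cv = pls.CVResult(["a", "b", "c"], np.array([0.0, 1.0, 2.0]),
                          np.array([0.0, 1.0, 2.0]), 0.0, 1, (0, 1))
        d = pls.regression_diagnostics(cv)
        assert d["slope"] == pytest.approx(1.0)
        assert d["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert d["r_squared"] == pytest.approx(1.0)

    def test_constant_bias_shows_in_intercept(self):
        y = np.linspace(0, 500, 20)
        cv = pls.CVResult([str(i) for i in range(20)], y, y + 25.0, 25.0, 1, (0, 1))
        d = pls.regression_diagnostics(cv)
        assert d["slope"] == pytest.approx(1.0)
        assert d["intercept"] == pytest.approx(25.0)

    def test_slope_covers_unity_on_low_noise_run(self, calibration_dataset):
        cv = pls.lopo_cv(calibration_dataset, n_factors=4)
        d = pls.regression_diagnostics(cv)
        assert abs(d["slope"] - 1.0) < 3 * d["slope_se"] + 0.01


class TestRandomizeLabels:
    def test_multiset_preserved_and_reproducible(self):
        ds = _toy_dataset()
        r1 = pls.randomize_labels(ds, 7)
        r2 = pls.randomize_labels(ds, 7)
        assert sorted(r1.y) == sorted(ds.y)
        assert np.array_equal(r1.y, r2.y)
        assert not np.array_equal(pls.randomize_labels(ds, 8).y, r1.y)

    def test_randomized_secv_near_label_sd(self, calibration_dataset):
        """Optimum-model SECV under label permutation ~ label SD (mean prediction)."""
        secvs = []
        for s in range(8):
            sh = pls.randomize_labels(calibration_dataset, s)
            _, curve = pls.lopo_cv_curve(sh, max_factors=20)
            secvs.append(curve.min())
        sd = np.std(calibration_dataset.y)
        assert np.mean(secvs) == pytest.approx(sd, rel=0.1)

    def test_secv_decreases_with_factors_only_for_correct_labels(self, calibration_dataset):
        """Bias-variance signature: true labels improve with factors, shuffled don't."""
        _, clean = pls.lopo_cv_curve(calibration_dataset, max_factors=12)
        assert clean[5] < clean[0]  # drops then plateaus
        sh = pls.randomize_labels(calibration_dataset, 3)
        _, rand = pls.lopo_cv_curve(sh, max_factors=12)
        assert rand[11] >= rand[0]
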