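import numpy as np
import pytest

from phantomnir import design, spectra


@pytest.fixture(scope="session")
def lib():
    return spectra.default_library()


@pytest.fixture(scope="session")
def grid112():
    return spectra.default_grid()


@pytest.fixture(scope="session")
def table1_design():
    return design.build_design()


@pytest.fixture(scope="session")
def phantom_mean_spectra(table1_design, grid112, lib):
    """49 phantom mean absorbance spectra at the two-minute-average noise level.

    Emulates the harmonized calibration dataset directly in the absorbance
    domain: per-phantom base spectrum plus a small thermostat offset and
    white noise at the level left after averaging ~900 scans of
    667.2/sqrt(2) µAU each (~15.6 µAU).
    """
    from phantomnir.preprocess import AbsorbanceSpectrum

    rng = np.random.default_rng(1234)
    dadt = lib.temperature_sensitivity(grid112.wavelengths)
    out = []
    for r in table1_design.recipes():
        a = spectra.simulate_absorbance(r.concentrations, grid112, lib)
        a = a + dadt * rng.normal(0.0, 0.1)
        a = a + rng.normal(0.0, 15.6e-6, size=len(grid112))
        out.append(AbsorbanceSpectrum(grid112, a, phantom_id=r.phantom_id))
    return out


@pytest.fixture(scope="session")
def calibration_dataset(phantom_mean_spectra, table1_design):
    from phantomnir import pls

    labels = table1_design.table["glucose_mgdl"].to_numpy()
    return pls.CalibrationDataset.from_spectra(phantom_mean_spectra, labels)
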