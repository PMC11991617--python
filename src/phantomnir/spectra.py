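"""Forward simulation of single-beam NIR spectra and laser modulation cycles.

The generator emulates diffuse-reflectance measurements of aqueous
scattering phantoms on two instrument profiles:

* a discrete-laser prototype: 112 wavelengths, each laser pulsed for
  200 µs with 300 µs dark periods between pulses, demodulated into one
  single-beam spectrum per modulation cycle;
* an FT-style reference instrument: a denser wavelength grid later
  interpolated down to the laser wavelengths.

The optical model is Beer–Lambert in absorbance:

    A(λ) = f_w · A_w(λ) + Σ_i ε_i(λ) c_i
           + s0·c_beads + s1·c_beads·(λ − λ_mid)
           + (dA/dT)(λ) · (T − T_ref)

with a water-displacement factor f_w = 1 − Σ_i κ_i c_i (solutes occupy
volume otherwise filled by water), a bead-scattering baseline that is
affine in wavelength, and a temperature-sensitivity curve.  Component
absorptivities are sums of Gaussian bands; all band parameters live in the
:class:`AbsorptivityLibrary`, not in code paths.

Noise, drift and temperature ramps are injected in the absorbance domain,
then mapped to intensities via I = I0 · 10^(−A).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavelengthGrid",
    "GaussianBand",
    "AbsorptivityLibrary",
    "SingleBeamSpectrum",
    "SpectralTimeSeries",
    "ModulationCycle",
    "default_grid",
    "default_library",
    "simulate_absorbance",
    "absorbance_to_single_beam",
    "simulate_time_series",
    "simulate_modulation_cycle",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis, nm, within 1300–2500 nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 1300.0 or wl[-1] > 2500.0:
            raise ValueError("wavelengths must lie within 1300–2500 nm")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __eq__(self, other) -> bool:  # value equality for grids
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )


def default_grid(n: int = 112, lo: float = 1350.0, hi: float = 2450.0) -> WavelengthGrid:
    """Uniform wavelength grid; default emulates the prototype's 112 lasers.

    The prototype's actual laser wavelengths are proprietary; a uniform
    112-point grid over 1350–2450 nm covers both the first-overtone
    (~1540–1820 nm) and combination (~2000–2500 nm) glucose regions.
    """
    return WavelengthGrid(np.linspace(lo, hi, n))


def dense_grid(n: int = 391, lo: float = 1330.0, hi: float = 2470.0) -> WavelengthGrid:
    """Denser grid emulating the FT instrument's 391 native resolution elements."""
    return WavelengthGrid(np.linspace(lo, hi, n))


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: amplitude · exp(−(λ−center)²/2σ²)."""

    center_nm: float
    sigma_nm: float
    amplitude: float

    def __call__(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.sigma_nm) ** 2)


def _sum_bands(bands: tuple[GaussianBand, ...], wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for b in bands:
        out += b(wl)
    return out


@dataclass(frozen=True)
class AbsorptivityLibrary:
    """Optical constants of the synthetic phantom model.

    All curves are analytic (sums of Gaussian bands) so the library is
    defined on any grid within ``span_nm``.  Solute absorptivities are in
    AU per mg/dL (pathlength folded in); the water curve and temperature
    sensitivity are in AU and AU/°C.

    Notes
    -----
    The library is synthetic: the study instrument's wavelengths and the
    phantoms' measured absorptivities are not public, so band positions
    follow the known NIR chemistry (glucose first-overtone bands near
    1590/1730 nm and combination bands near 2100/2270 nm; water bands near
    1450/1940 nm) while amplitudes are set so a 500 mg/dL glucose step
    produces a signal of order 100 µAU — small against the water
    background, which is what makes the calibration realistically hard.
    """

    solute_bands: dict[str, tuple[GaussianBand, ...]]
    water_bands: tuple[GaussianBand, ...]
    temp_bands: tuple[GaussianBand, ...]  # dA/dT, AU per °C
    displacement_per_mgdl: dict[str, float]  # water volume fraction lost per mg/dL
    scatter_offset_per_mgdl: float  # AU per mg/dL beads
    scatter_slope_per_mgdl_nm: float  # AU per mg/dL beads per nm, about lambda_mid
    lambda_mid_nm: float = 1900.0
    t_ref_c: float = 32.0
    span_nm: tuple[float, float] = (1300.0, 2500.0)

    def absorptivity(self, component: str, wl: np.ndarray) -> np.ndarray:
        """ε_component(λ) in AU/(mg/dL); zero for components with no bands."""
        bands = self.solute_bands.get(component, ())
        return _sum_bands(tuple(bands), np.asarray(wl, float))

    def water_absorbance(self, wl: np.ndarray) -> np.ndarray:
        return _sum_bands(self.water_bands, np.asarray(wl, float))

    def temperature_sensitivity(self, wl: np.ndarray) -> np.ndarray:
        return _sum_bands(self.temp_bands, np.asarray(wl, float))

    def check_grid(self, grid: WavelengthGrid) -> None:
        lo, hi = grid.span
        if lo < self.span_nm[0] or hi > self.span_nm[1]:
            raise ValueError(
                f"grid span {grid.span} outside library span {self.span_nm}"
            )


def default_library() -> AbsorptivityLibrary:
    """Default optical model (see class notes for the rationale)."""
    glucose = (
        GaussianBand(1590.0, 35.0, 4.0e-8),
        GaussianBand(1730.0, 30.0, 6.0e-8),
        GaussianBand(2100.0, 40.0, 2.0e-7),
        GaussianBand(2270.0, 35.0, 1.6e-7),
    )
    # Triton/saline absorb weakly and are constant across the design, so
    # they fold into the baseline; small C-H bands are still modeled so
    # recipe perturbations have a spectral signature.
    triton = (GaussianBand(1720.0, 45.0, 3.0e-8), GaussianBand(2310.0, 50.0, 4.0e-8))
    saline = (GaussianBand(1940.0, 80.0, -1.0e-8),)  # ionic perturbation of water band
    germall = (GaussianBand(2050.0, 60.0, 2.0e-8),)
    water = (
        GaussianBand(1450.0, 55.0, 0.55),
        GaussianBand(1940.0, 70.0, 1.25),
        GaussianBand(2500.0, 180.0, 0.9),
    )
    # Water-band temperature shift: derivative-like feature around each
    # water band, order 1e-4 AU/°C.
    temp = (
        GaussianBand(1412.0, 40.0, 1.5e-4),
        GaussianBand(1486.0, 40.0, -1.2e-4),
        GaussianBand(1900.0, 50.0, 2.5e-4),
        GaussianBand(1985.0, 50.0, -2.0e-4),
    )
    # Volume displacement: c mg/dL = c·1e-5 g/mL; partial specific volumes
    # ~0.6–0.95 mL/g give kappa = v̄·1e-5 per mg/dL.
    displacement = {
        "glucose": 0.63e-5,
        "triton": 0.91e-5,
        "saline": 0.30e-5,
        "germall": 0.80e-5,
        "beads": 0.95e-5,
    }
    return AbsorptivityLibrary(
        solute_bands={"glucose": glucose, "triton": triton,
                      "saline": saline, "germall": germall},
        water_bands=water,
        temp_bands=temp,
        displacement_per_mgdl=displacement,
        scatter_offset_per_mgdl=1.0e-5,
        scatter_slope_per_mgdl_nm=2.0e-9,
    )


@dataclass
class SingleBeamSpectrum:
    """Raw detector intensity versus wavelength for one scan."""

    grid: WavelengthGrid
    intensities: np.ndarray
    timestamp_s: float = 0.0
    scan_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError("intensity vector length must match the wavelength grid")
        if np.any(self.intensities <= 0):
            raise ValueError("single-beam intensities must be positive")


@dataclass
class SpectralTimeSeries:
    """Ordered scans of one phantom at a uniform scan rate."""

    scans: list[SingleBeamSpectrum]
    scan_rate: float  # scans per second
    phantom_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.scans) >= 2:
            dt = np.diff([s.timestamp_s for s in self.scans])
            if np.any(dt <= 0):
                raise ValueError("scan timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.scan_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced at 1/scan_rate")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def grid(self) -> WavelengthGrid:
        return self.scans[0].grid

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp_s for s in self.scans])

    def intensity_matrix(self) -> np.ndarray:
        """Scans x wavelengths intensity matrix."""
        return np.vstack([s.intensities for s in self.scans])


@dataclass
class ModulationCycle:
    """One pulsed-laser modulation cycle: the raw detector stream.

    ``laser_index`` is −1 during dark periods and the 0-based laser index
    (in order of increasing wavelength) during each 200 µs on-pulse.
    """

    time_us: np.ndarray
    laser_index: np.ndarray
    values: np.ndarray
    sample_interval_us: float
    grid: WavelengthGrid
    pulse_us: float = 200.0
    dark_us: float = 300.0

    def __post_init__(self) -> None:
        n = len(self.time_us)
        if not (len(self.laser_index) == len(self.values) == n):
            raise ValueError("time, laser_index and values must have equal length")


def simulate_absorbance(
    recipe,
    grid: WavelengthGrid,
    lib: AbsorptivityLibrary,
    temperature_c: float | None = None,
) -> np.ndarray:
    """Noise-free absorbance spectrum of one phantom, AU.

    ``recipe`` is a :class:`~phantomnir.design.PhantomRecipe` or a plain
    mapping of component name to concentration (mg/dL); the ``beads``
    entry drives the scattering baseline, every other entry is a solute.
    """
    lib.check_grid(grid)
    conc = dict(getattr(recipe, "concentrations", recipe))
    if any(c < 0 for c in conc.values()):
        raise ValueError("component concentrations must be non-negative")
    wl = grid.wavelengths
    beads = conc.pop("beads", 0.0)

    f_water = 1.0 - sum(
        lib.displacement_per_mgdl.get(name, 0.0) * c for name, c in conc.items()
    ) - lib.displacement_per_mgdl.get("beads", 0.0) * beads
    a = lib.water_absorbance(wl) * f_water
    for name, c in conc.items():
        if c:
            a = a + lib.absorptivity(name, wl) * c
    a = a + lib.scatter_offset_per_mgdl * beads
    a = a + lib.scatter_slope_per_mgdl_nm * beads * (wl - lib.lambda_mid_nm)
    if temperature_c is None:
        temperature_c = lib.t_ref_c
    a = a + lib.temperature_sensitivity(wl) * (temperature_c - lib.t_ref_c)
    return a


def absorbance_to_single_beam(
    absorbance: np.ndarray,
    grid: WavelengthGrid,
    reference_intensity: np.ndarray | float = 1.0,
    timestamp_s: float = 0.0,
    scan_duration_s: float | None = None,
) -> SingleBeamSpectrum:
    """Map absorbance to intensity, I = I0 · 10^(−A)."""
    i0 = np.broadcast_to(np.asarray(reference_intensity, float), (len(grid),))
    return SingleBeamSpectrum(grid, i0 * 10.0 ** (-np.asarray(absorbance, float)),
                              timestamp_s=timestamp_s, scan_duration_s=scan_duration_s)


def simulate_time_series(
    recipe,
    grid: WavelengthGrid,
    lib: AbsorptivityLibrary,
    duration_s: float,
    scan_rate: float,
    noise_rms_uau: float = 0.0,
    drift_au_per_min: float = 0.0,
    temp_drift_c_per_min: float = 0.0,
    seed: int | None = None,
    temperature_c: float | None = None,
    reference_intensity: np.ndarray | float = 1000.0,
    phantom_id: str | None = None,
) -> SpectralTimeSeries:
    """Simulate repeated scans of one phantom.

    Per scan and wavelength, independent Gaussian noise of the given
    absorbance-equivalent RMS (µAU) is added, plus an optional linear
    baseline drift (AU/min) and a temperature ramp (°C/min) acting through
    the library's temperature-sensitivity curve.  The scan count is
    floor(duration · scan_rate).
    """
    if noise_rms_uau < 0:
        raise ValueError("noise_rms_uau must be non-negative")
    n_scans = int(np.floor(duration_s * scan_rate))
    if n_scans < 2:
        raise ValueError("duration * scan_rate must allow at least 2 scans")
    rng = np.random.default_rng(seed)
    base = simulate_absorbance(recipe, grid, lib, temperature_c=temperature_c)
    dadt = lib.temperature_sensitivity(grid.wavelengths)
    sigma_au = noise_rms_uau * 1e-6
    scan_duration = 1.0 / scan_rate

    scans = []
    for j in range(n_scans):
        t = j / scan_rate
        a = base + drift_au_per_min * (t / 60.0)
        if temp_drift_c_per_min:
            a = a + dadt * temp_drift_c_per_min * (t / 60.0)
        if sigma_au:
            a = a + rng.normal(0.0, sigma_au, size=len(grid))
        scans.append(
            absorbance_to_single_beam(a, grid, reference_intensity,
                                      timestamp_s=t, scan_duration_s=scan_duration)
        )
    pid = phantom_id or getattr(recipe, "phantom_id", None)
    return SpectralTimeSeries(scans, scan_rate, phantom_id=pid)


def simulate_modulation_cycle(
    spectrum: SingleBeamSpectrum,
    dark_level: float = 0.0,
    pulse_us: float = 200.0,
    dark_us: float = 300.0,
    sample_interval_us: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ModulationCycle:
    """Expand one single-beam spectrum into the raw pulsed detector stream.

    Lasers fire in order of increasing wavelength, each on-pulse flanked
    by shared dark periods: dark, laser 1, dark, laser 2, ..., dark.
    On-samples have mean ``dark_level + intensity``; dark samples have
    mean ``dark_level``.
    """
    for name, dur in (("pulse", pulse_us), ("dark", dark_us)):
        if abs(dur / sample_interval_us - round(dur / sample_interval_us)) > 1e-9:
            raise ValueError(
                f"sample interval {sample_interval_us} µs does not divide the "
                f"{name} duration {dur} µs"
            )
    n_on = int(round(pulse_us / sample_interval_us))
    n_dark = int(round(dark_us / sample_interval_us))
    rng = np.random.default_rng(seed)

    idx_chunks = [np.full(n_dark, -1, dtype=int)]
    mean_chunks = [np.full(n_dark, dark_level, dtype=float)]
    for li, intensity in enumerate(spectrum.intensities):
        idx_chunks.append(np.full(n_on, li, dtype=int))
        mean_chunks.append(np.full(n_on, dark_level + intensity))
        idx_chunks.append(np.full(n_dark, -1, dtype=int))
        mean_chunks.append(np.full(n_dark, dark_level, dtype=float))
    laser_index = np.concatenate(idx_chunks)
    values = np.concatenate(mean_chunks)
    if noise_sd:
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    time_us = np.arange(values.size) * sample_interval_us
    return ModulationCycle(time_us, laser_index, values, sample_interval_us,
                           spectrum.grid, pulse_us=pulse_us, dark_us=dark_us)
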