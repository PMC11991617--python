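"""100% line RMS-noise and SNR benchmarking.

A 100% line is the negative base-10 logarithm of the ratio of two
back-to-back single-beam spectra of the same sample — ideally flat at
zero absorbance, in practice offset, curved and noisy.  Offset and
curvature (scattering and temperature differences between the two scans)
are removed with a second-order polynomial fit; the residual quantifies
instrument + interface noise:

    RMS noise = sqrt( Σ y_i² / (N − 1 − k) )        [reported in µAU]
    SNR       = (2.303 · RMS noise)⁻¹                [RMS in AU]

with N the number of wavelengths and k the polynomial order.  Under white
noise, averaging n scans scales the RMS by 1/sqrt(n), which converts
single-scan noise to an equivalent longer-measurement figure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra import SingleBeamSpectrum, SpectralTimeSeries, WavelengthGrid

__all__ = [
    "HundredPercentLine",
    "RMSNoiseResult",
    "hundred_percent_line",
    "detrend",
    "rms_noise",
    "snr",
    "scale_rms_to_duration",
    "benchmark_dataset",
    "calibrate_injection_noise",
    "add_absorbance_noise",
]

log = logging.getLogger(__name__)


@dataclass
class HundredPercentLine:
    """A (possibly detrended) ratio spectrum of two back-to-back scans."""

    grid: WavelengthGrid
    values: np.ndarray  # AU
    k: int | None = None  # polynomial order used for detrending
    coefficients: np.ndarray | None = None  # fitted poly coefficients (scaled domain)
    residuals: np.ndarray | None = None  # values - fitted polynomial, AU
    source_scans: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("100% line length must match the wavelength grid")


@dataclass
class RMSNoiseResult:
    """Per-line RMS noise values for a dataset, with summary statistics (µAU)."""

    per_phantom: dict[str, np.ndarray]
    n_wavelengths: int
    k: int
    all_rms: np.ndarray = field(init=False)
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)

    def __post_init__(self) -> None:
        vals = ([np.asarray(v, float) for v in self.per_phantom.values()]
                or [np.empty(0)])
        self.all_rms = np.concatenate(vals)
        if self.all_rms.size:
            self.median = float(np.median(self.all_rms))
            self.q1, self.q3 = (float(q) for q in np.percentile(self.all_rms, [25, 75]))
        else:
            self.median = self.q1 = self.q3 = float("nan")

    @property
    def median_snr(self) -> float:
        return snr(self.median)


def hundred_percent_line(
    s1: SingleBeamSpectrum, s2: SingleBeamSpectrum,
    source_scans: tuple[int, int] | None = None,
) -> HundredPercentLine:
    """y(λ) = −log10(I1/I2) for two back-to-back scans on the same grid."""
    if s1.grid != s2.grid:
        raise ValueError("both spectra must share one wavelength grid")
    y = -np.log10(s1.intensities / s2.intensities)
    return HundredPercentLine(s1.grid, y, source_scans=source_scans)


def detrend(
    line: HundredPercentLine, k: int = 2, regressor: str = "wavelength"
) -> HundredPercentLine:
    """Fit an order-k polynomial to the line and store the residuals.

    The regressor is the wavelength in nm (or the point index, if
    ``regressor="index"``), mapped internally to [−1, 1] for
    conditioning.  With k=2 this removes the offset and curvature of the
    raw line, leaving the noise.
    """
    if regressor == "wavelength":
        x = line.grid.wavelengths
    elif regressor == "index":
        x = np.arange(len(line.grid), dtype=float)
    else:
        raise ValueError(f"unknown regressor '{regressor}'")
    poly = np.polynomial.Polynomial.fit(x, line.values, deg=k)
    fitted = poly(x)
    return HundredPercentLine(
        line.grid, line.values, k=k,
        coefficients=poly.coef, residuals=line.values - fitted,
        source_scans=line.source_scans,
    )


def rms_noise(line: HundredPercentLine, k: int | None = None) -> float:
    """Eq-style RMS of the detrended residuals: sqrt(Σy²/(N−1−k)), in µAU.

    The denominator N−1−k is used verbatim (k=2 gives N−3).
    """
    if line.residuals is None:
        raise ValueError("line must be detrended before computing RMS noise")
    if k is None:
        k = line.k
    n = line.residuals.size
    dof = n - 1 - k
    if dof < 1:
        raise ValueError(f"need N > k + 1 wavelengths (N={n}, k={k})")
    return float(np.sqrt(np.sum(line.residuals**2) / dof) * 1e6)


def snr(rms_uau: float) -> float:
    """Signal-to-noise ratio: (2.303 × RMS)⁻¹ with RMS in AU."""
    if rms_uau == 0:
        return float("inf")
    return 1.0 / (2.303 * rms_uau * 1e-6)


def scale_rms_to_duration(rms_uau: float, n_scans_averaged: float) -> float:
    """White-noise scaling of RMS noise when n scans are averaged: rms/√n.

    Fractional scan counts (e.g. 8.33 scans/s × 60 s = 499.8) are used
    as-is.
    """
    if n_scans_averaged <= 0:
        raise ValueError("n_scans_averaged must be positive")
    return rms_uau / np.sqrt(n_scans_averaged)


def lines_from_series(
    series: SpectralTimeSeries, k: int = 2, pairing: str = "consecutive",
    regressor: str = "wavelength",
) -> list[HundredPercentLine]:
    """Detrended 100% lines from sequential scans of one phantom.

    ``pairing="consecutive"`` ratioes non-overlapping pairs (1,2), (3,4),
    ... so that lines are independent under white noise;
    ``pairing="sliding"`` ratioes every adjacent pair.
    """
    n = len(series)
    if pairing == "consecutive":
        pairs = [(2 * p, 2 * p + 1) for p in range(n // 2)]
    elif pairing == "sliding":
        pairs = [(i, i + 1) for i in range(n - 1)]
    else:
        raise ValueError(f"unknown pairing '{pairing}'")
    out = []
    for i, j in pairs:
        raw = hundred_percent_line(series.scans[i], series.scans[j], source_scans=(i, j))
        out.append(detrend(raw, k=k, regressor=regressor))
    return out


def benchmark_dataset(
    series_by_phantom: dict[str, SpectralTimeSeries] | list[SpectralTimeSeries],
    k: int = 2,
    pairing: str = "consecutive",
    regressor: str = "wavelength",
) -> RMSNoiseResult:
    """Per-phantom 100% line RMS noise distributions and dataset summary."""
    if not isinstance(series_by_phantom, dict):
        series_by_phantom = {
            (s.phantom_id or f"phantom{i:02d}"): s
            for i, s in enumerate(series_by_phantom)
        }
    per_phantom = {}
    n_wl = None
    for pid, series in series_by_phantom.items():
        lines = lines_from_series(series, k=k, pairing=pairing, regressor=regressor)
        per_phantom[pid] = np.array([rms_noise(l) for l in lines])
        n_wl = len(series.grid)
    return RMSNoiseResult(per_phantom, n_wavelengths=int(n_wl or 0), k=k)


def add_absorbance_noise(
    series: SpectralTimeSeries, sigma_au: float, rng: np.random.Generator
) -> SpectralTimeSeries:
    """Return a copy of the series with Gaussian absorbance noise added."""
    scans = []
    for s in series.scans:
        noisy = s.intensities * 10.0 ** (-rng.normal(0.0, sigma_au, size=len(s.grid)))
        scans.append(SingleBeamSpectrum(s.grid, noisy, timestamp_s=s.timestamp_s,
                                        scan_duration_s=s.scan_duration_s))
    return SpectralTimeSeries(scans, series.scan_rate, phantom_id=series.phantom_id)


def calibrate_injection_noise(
    series_by_phantom: dict[str, SpectralTimeSeries],
    target_median_rms_uau: float,
    tol_uau: float = 1.0,
    seed: int | None = None,
    k: int = 2,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Find the Gaussian absorbance-noise level matching a target median RMS.

    Bisects on the added noise sigma (AU), evaluating the dataset median
    Eq-style RMS with a fixed noise realization (one seed, redrawn
    identically per evaluation) so the objective is monotone in sigma.
    Returns ``(sigma_au, achieved_median_uau)``.

    Raises
    ------
    ValueError
        If the target lies below the dataset's baseline median RMS.
    """

    def median_at(sigma: float) -> float:
        rng = np.random.default_rng(seed)
        noisy = {pid: add_absorbance_noise(s, sigma, rng)
                 for pid, s in series_by_phantom.items()}
        return benchmark_dataset(noisy, k=k).median

    baseline = benchmark_dataset(series_by_phantom, k=k).median
    if target_median_rms_uau < baseline - tol_uau:
        raise ValueError(
            f"target median {target_median_rms_uau} µAU is below the baseline "
            f"median {baseline:.1f} µAU; noise cannot be removed"
        )
    if abs(baseline - target_median_rms_uau) <= tol_uau:
        return 0.0, baseline

    lo, hi = 0.0, target_median_rms_uau * 1e-6 * 2.0
    while median_at(hi) < target_median_rms_uau and hi < 1.0:
        hi *= 2.0
    achieved = baseline
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved = median_at(mid)
        if abs(achieved - target_median_rms_uau) <= tol_uau:
            return mid, achieved
        if achieved < target_median_rms_uau:
            lo = mid
        else:
            hi = mid
    log.warning("injection-noise bisection hit max_iter; achieved %.2f µAU", achieved)
    return 0.5 * (lo + hi), achieved
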