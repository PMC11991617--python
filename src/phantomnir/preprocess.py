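"""Harmonization of raw instrument data into comparable absorbance spectra.

The two instrument profiles differ in wavelength axis, sampling rate and
acquisition duration, so raw data are harmonized before any comparison:

* modulation cycles are demodulated — per laser, the mean on-signal minus
  the mean of the 100 µs of dark signal immediately before and after the
  pulse;
* consecutive scan pairs are averaged to halve the prototype's 15.15
  scans/s rate to 7.58 scans/s, close to the reference's 8.33 scans/s;
* the first and last 2.5 min of the prototype's 7-min acquisition are
  trimmed, leaving the middle two minutes to match the reference;
* dense-grid spectra are interpolated onto the laser wavelengths with a
  shape-preserving piecewise cubic (PCHIP);
* intensities become absorbance via A = −log10(I/I0), and per-phantom
  scans are averaged into a single two-minute spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .spectra import (
    ModulationCycle,
    SingleBeamSpectrum,
    SpectralTimeSeries,
    WavelengthGrid,
)

__all__ = [
    "AbsorbanceSpectrum",
    "demodulate",
    "pairwise_average",
    "trim_to_window",
    "resample_to_grid",
    "to_absorbance",
    "phantom_mean_spectrum",
]


@dataclass
class AbsorbanceSpectrum:
    """Absorbance (AU) versus wavelength, possibly an average of many scans."""

    grid: WavelengthGrid
    values: np.ndarray
    phantom_id: str | None = None
    n_scans_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("absorbance vector length must match the wavelength grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorbance values must be finite")


def demodulate(cycle: ModulationCycle, dark_window_us: float = 100.0) -> SingleBeamSpectrum:
    """Convert one modulation cycle into a single-beam spectrum.

    Per laser, V = mean(on-samples) − mean(dark samples within the
    ``dark_window_us`` windows immediately before and after the pulse).
    Output is ordered by increasing wavelength (the pulsing order).
    """
    n_window = int(round(dark_window_us / cycle.sample_interval_us))
    n_lasers = len(cycle.grid)
    idx = cycle.laser_index
    out = np.empty(n_lasers)
    for li in range(n_lasers):
        on = np.flatnonzero(idx == li)
        if on.size == 0:
            raise ValueError(f"laser {li}: no on-samples in modulation cycle")
        start, stop = on[0], on[-1] + 1
        before = np.arange(start - n_window, start)
        after = np.arange(stop, stop + n_window)
        if before[0] < 0 or after[-1] >= idx.size or np.any(idx[before] != -1) or np.any(idx[after] != -1):
            raise ValueError(
                f"laser {li}: missing {dark_window_us} µs flanking dark segment"
            )
        dark = np.concatenate([cycle.values[before], cycle.values[after]]).mean()
        out[li] = cycle.values[on].mean() - dark
    return SingleBeamSpectrum(cycle.grid, out)


def pairwise_average(series: SpectralTimeSeries) -> SpectralTimeSeries:
    """Average non-overlapping consecutive scan pairs; halves the scan rate.

    A trailing odd scan is dropped so every output scan is an equal-weight
    two-scan average.  The output timestamp of a pair is the midpoint of
    its members' timestamps.
    """
    if len(series) < 2:
        raise ValueError("pairwise averaging needs at least 2 scans")
    n_pairs = len(series) // 2
    out = []
    for p in range(n_pairs):
        s1, s2 = series.scans[2 * p], series.scans[2 * p + 1]
        out.append(
            SingleBeamSpectrum(
                s1.grid,
                0.5 * (s1.intensities + s2.intensities),
                timestamp_s=0.5 * (s1.timestamp_s + s2.timestamp_s),
                scan_duration_s=None if s1.scan_duration_s is None else 2 * s1.scan_duration_s,
            )
        )
    return SpectralTimeSeries(out, series.scan_rate / 2.0, phantom_id=series.phantom_id)


def trim_to_window(
    series: SpectralTimeSeries, keep_start_s: float = 150.0, keep_end_s: float = 270.0
) -> SpectralTimeSeries:
    """Keep scans with keep_start_s <= t < keep_end_s (relative to the first scan).

    The defaults drop the first and last 2.5 minutes of a 7-minute
    acquisition, retaining the middle two minutes.
    """
    if keep_end_s <= keep_start_s:
        raise ValueError("keep_end_s must exceed keep_start_s")
    t0 = series.scans[0].timestamp_s
    kept = [s for s in series.scans
            if keep_start_s <= s.timestamp_s - t0 < keep_end_s]
    if not kept:
        raise ValueError(
            f"no scans remain in window [{keep_start_s}, {keep_end_s}) s"
        )
    return SpectralTimeSeries(kept, series.scan_rate, phantom_id=series.phantom_id)


def resample_to_grid(
    spectrum: SingleBeamSpectrum, target: WavelengthGrid
) -> SingleBeamSpectrum:
    """Interpolate a spectrum onto a target grid (shape-preserving cubic).

    Uses monotone piecewise-cubic Hermite interpolation (PCHIP), which
    never overshoots beyond the bracketing data values.  Extrapolation is
    refused.
    """
    lo, hi = spectrum.grid.span
    tlo, thi = target.span
    if tlo < lo or thi > hi:
        raise ValueError(
            f"target span ({tlo}, {thi}) nm outside source span ({lo}, {hi}) nm"
        )
    interp = PchipInterpolator(spectrum.grid.wavelengths, spectrum.intensities)
    return SingleBeamSpectrum(
        target, interp(target.wavelengths),
        timestamp_s=spectrum.timestamp_s, scan_duration_s=spectrum.scan_duration_s,
    )


def to_absorbance(obj, reference="unit"):
    """Transform intensity to absorbance, A = −log10(I/I0).

    ``reference`` may be "unit" (I0 = 1, i.e. A = −log10 I — any common
    reference cancels in 100% lines and is absorbed by model centering),
    a scalar, or a per-wavelength array.  Accepts one
    :class:`SingleBeamSpectrum` (returns one :class:`AbsorbanceSpectrum`)
    or a :class:`SpectralTimeSeries` (returns a list, one per scan).
    """
    if isinstance(obj, SpectralTimeSeries):
        return [to_absorbance(s, reference) for s in obj.scans]
    spectrum: SingleBeamSpectrum = obj
    i = spectrum.intensities
    i0 = 1.0 if isinstance(reference, str) and reference == "unit" else np.asarray(reference, float)
    ratio = i / i0
    if np.any(ratio <= 0):
        bad = spectrum.grid.wavelengths[np.asarray(ratio <= 0).nonzero()]
        raise ValueError(f"nonpositive intensity ratio at wavelengths (nm): {bad.tolist()}")
    return AbsorbanceSpectrum(spectrum.grid, -np.log10(ratio))


def phantom_mean_spectrum(
    absorbances: list[AbsorbanceSpectrum], phantom_id: str | None = None
) -> AbsorbanceSpectrum:
    """Arithmetic mean over scans, per wavelength; records the scan count."""
    if not absorbances:
        raise ValueError("cannot average an empty list of spectra")
    grid = absorbances[0].grid
    stack = np.vstack([a.values for a in absorbances])
    return AbsorbanceSpectrum(
        grid, stack.mean(axis=0),
        phantom_id=phantom_id or absorbances[0].phantom_id,
        n_scans_averaged=len(absorbances),
    )
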