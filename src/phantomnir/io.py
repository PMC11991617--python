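"""CSV/JSON serialization of spectra, designs and benchmark results.

Spectra use a wide CSV dialect: a header row of wavelengths in nm, one
row per scan prefixed by ``timestamp_s``, plus a JSON sidecar carrying
phantom id, scan rate and generator provenance.  Modulation cycles are
long CSVs of (time_us, laser_index, value) with laser_index −1 during
dark periods.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import (
    ModulationCycle,
    SingleBeamSpectrum,
    SpectralTimeSeries,
    WavelengthGrid,
)

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_modulation_csv",
    "read_modulation_csv",
    "write_json",
]


def write_series_csv(series: SpectralTimeSeries, path, sidecar: dict | None = None) -> None:
    """Write a spectral time series as wide CSV (+ optional JSON sidecar)."""
    path = Path(path)
    cols = ["timestamp_s"] + [f"{w:.6f}" for w in series.grid.wavelengths]
    rows = [[s.timestamp_s, *s.intensities] for s in series.scans]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = {"phantom_id": series.phantom_id, "scan_rate": series.scan_rate}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_series_csv(path) -> SpectralTimeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    grid = WavelengthGrid(np.array([float(c) for c in df.columns[1:]]))
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    scan_rate = meta.get("scan_rate")
    t = df["timestamp_s"].to_numpy()
    if scan_rate is None:
        scan_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    scans = [
        SingleBeamSpectrum(grid, row, timestamp_s=float(ts))
        for ts, row in zip(t, df.iloc[:, 1:].to_numpy())
    ]
    return SpectralTimeSeries(scans, float(scan_rate), phantom_id=meta.get("phantom_id"))


def write_modulation_csv(cycle: ModulationCycle, path) -> None:
    pd.DataFrame({
        "time_us": cycle.time_us,
        "laser_index": cycle.laser_index,
        "value": cycle.values,
    }).to_csv(path, index=False)


def read_modulation_csv(path, grid: WavelengthGrid,
                        sample_interval_us: float | None = None) -> ModulationCycle:
    df = pd.read_csv(path)
    t = df["time_us"].to_numpy(float)
    if sample_interval_us is None:
        sample_interval_us = float(np.median(np.diff(t)))
    return ModulationCycle(t, df["laser_index"].to_numpy(int),
                           df["value"].to_numpy(float), sample_interval_us, grid)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
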