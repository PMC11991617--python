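"""Run configuration: validated, YAML-serializable study parameters.

Defaults encode the benchmark study's conditions: the printed 7-level
design, a 112-wavelength laser profile (15.15 scans/s, 7 min) and a
391-point FT profile (8.33 scans/s, 2 min), with per-scan absorbance
noise sized so the harmonized datasets reproduce the reported 100% line
median RMS levels (667.2 µAU laser, 327.8 µAU FT).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .design import BEAD_LEVELS, GLUCOSE_LEVELS

__all__ = ["RunConfig", "DesignConfig", "GeneratorConfig", "PreprocessConfig",
           "BenchmarkConfig", "PLSConfig"]

# Per-scan absorbance noise RMS (µAU).  A 100% line is the log-ratio of
# two scans, so its RMS is sqrt(2) x the per-scan RMS; the laser profile's
# raw scans are additionally pairwise-averaged (another 1/sqrt(2)) before
# lines are formed.  These values therefore land the harmonized datasets
# on median line RMS of 667.2 and 327.8 µAU respectively.
LASER_SCAN_NOISE_UAU = 667.2
FT_SCAN_NOISE_UAU = 327.8 / 2 ** 0.5


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass
class DesignConfig:
    glucose_levels: list = field(default_factory=lambda: list(GLUCOSE_LEVELS))
    bead_levels: list = field(default_factory=lambda: list(BEAD_LEVELS))


@dataclass
class GeneratorConfig:
    n_wavelengths: int = 112
    wl_min_nm: float = 1350.0
    wl_max_nm: float = 2450.0
    ft_points: int = 391
    ft_wl_min_nm: float = 1330.0
    ft_wl_max_nm: float = 2470.0
    laser_scan_rate: float = 15.15
    laser_duration_s: float = 420.0
    ft_scan_rate: float = 8.33
    ft_duration_s: float = 120.0
    laser_noise_rms_uau: float = LASER_SCAN_NOISE_UAU
    ft_noise_rms_uau: float = FT_SCAN_NOISE_UAU
    drift_au_per_min: float = 1.0e-4
    temp_drift_c_per_min: float = 0.05
    reference_intensity: float = 1000.0
    dark_level: float = 5.0
    sample_interval_us: float = 10.0
    # per-phantom nuisance: thermostat reproducibility and gravimetric
    # dispensing error (relative), drawn once per phantom measurement
    temp_offset_sd_c: float = 0.1
    recipe_error_rel: float = 0.002

    def __post_init__(self) -> None:
        if self.n_wavelengths < 4 or self.ft_points < 4:
            raise ValueError("grids need at least 4 points")
        for name in ("laser_noise_rms_uau", "ft_noise_rms_uau",
                     "laser_scan_rate", "ft_scan_rate",
                     "laser_duration_s", "ft_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PreprocessConfig:
    pairwise_average: bool = True
    trim_start_s: float = 150.0
    trim_end_s: float = 270.0


@dataclass
class BenchmarkConfig:
    detrend_order: int = 2
    pairing: str = "consecutive"
    regressor: str = "wavelength"

    def __post_init__(self) -> None:
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        if self.pairing not in ("consecutive", "sliding"):
            raise ValueError(f"unknown pairing '{self.pairing}'")


@dataclass
class PLSConfig:
    min_width_nm: float = 50.0
    width_step_nm: float = 50.0
    start_step_nm: float = 50.0
    max_factors: int = 20
    n_factors: int = 8  # for fixed-factor cross-validation runs

    def __post_init__(self) -> None:
        if not 1 <= self.n_factors <= self.max_factors:
            raise ValueError("need 1 <= n_factors <= max_factors")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    design: DesignConfig = field(default_factory=DesignConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    pls: PLSConfig = field(default_factory=PLSConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "design": DesignConfig, "generator": GeneratorConfig,
            "preprocess": PreprocessConfig, "benchmark": BenchmarkConfig,
            "pls": PLSConfig,
        }
        kwargs = {}
        for key, sub_cls in sections.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data.pop(key) or {})
        unknown = set(data) - {"seed", "out_dir"}
        if unknown:
            raise KeyError(f"unknown RunConfig key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})
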