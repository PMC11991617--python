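"""End-to-end study drivers: simulate, harmonize, benchmark, calibrate.

These functions chain the package's modules into the benchmarking
workflow: build the 49-phantom design, forward-simulate both instrument
profiles, harmonize raw data onto a common 112-wavelength / two-minute
footing, benchmark 100% line RMS noise, and run the PLS calibration
analyses (grid search, fixed-factor cross-validation, noise injection,
randomized-label control).  The CLI and the numbered analysis drivers are
thin wrappers around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io, noise, pls, preprocess
from .config import RunConfig
from .design import DesignTable, build_design
from .spectra import (
    AbsorptivityLibrary,
    SpectralTimeSeries,
    WavelengthGrid,
    default_library,
    simulate_time_series,
)

__all__ = [
    "StudyData",
    "simulate_study",
    "harmonize_laser",
    "harmonize_ft",
    "build_calibration_dataset",
    "run_benchmark",
    "run_calibrate",
    "run_randomization_control",
    "run_simulate_to_dir",
]

log = logging.getLogger(__name__)


def _phantom_seeds(seed: int, n: int, stream: int) -> list[int]:
    """Independent 31-bit child seeds for each phantom of one profile."""
    ss = np.random.SeedSequence([seed, stream])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class StudyData:
    """Raw and harmonized synthetic study data for one or both profiles."""

    design: DesignTable
    grid: WavelengthGrid
    raw: dict[str, dict[str, SpectralTimeSeries]]  # profile -> phantom -> series
    harmonized: dict[str, dict[str, SpectralTimeSeries]]
    datasets: dict[str, pls.CalibrationDataset]


def laser_grid(cfg: RunConfig) -> WavelengthGrid:
    g = cfg.generator
    return WavelengthGrid(np.linspace(g.wl_min_nm, g.wl_max_nm, g.n_wavelengths))


def ft_grid(cfg: RunConfig) -> WavelengthGrid:
    g = cfg.generator
    return WavelengthGrid(np.linspace(g.ft_wl_min_nm, g.ft_wl_max_nm, g.ft_points))


def simulate_study(
    cfg: RunConfig,
    profiles: tuple[str, ...] = ("ft", "laser"),
    lib: AbsorptivityLibrary | None = None,
) -> StudyData:
    """Simulate, harmonize and package the synthetic study in memory."""
    lib = lib or default_library()
    g = cfg.generator
    design = build_design(cfg.design.glucose_levels, cfg.design.bead_levels)
    recipes = design.recipes()
    target = laser_grid(cfg)

    raw: dict[str, dict[str, SpectralTimeSeries]] = {}
    harmonized: dict[str, dict[str, SpectralTimeSeries]] = {}
    datasets: dict[str, pls.CalibrationDataset] = {}
    streams = {"ft": 0, "laser": 1}  # fixed per profile so seeds do not
    # depend on which subset of profiles is simulated
    for profile in profiles:
        stream = streams.get(profile)
        if stream is None:
            raise ValueError(f"unknown profile '{profile}'")
        if profile == "laser":
            grid, rate, dur, noise_uau = target, g.laser_scan_rate, g.laser_duration_s, g.laser_noise_rms_uau
        else:
            grid, rate, dur, noise_uau = ft_grid(cfg), g.ft_scan_rate, g.ft_duration_s, g.ft_noise_rms_uau
        seeds = _phantom_seeds(cfg.seed, len(recipes), stream)
        raw[profile] = {}
        harmonized[profile] = {}
        means = []
        for recipe, s in zip(recipes, seeds):
            nuisance = np.random.default_rng(s + 1)
            conc = {
                name: max(0.0, c * (1.0 + nuisance.normal(0.0, g.recipe_error_rel)))
                for name, c in recipe.concentrations.items()
            }
            temp = lib.t_ref_c + nuisance.normal(0.0, g.temp_offset_sd_c)
            series = simulate_time_series(
                conc, grid, lib, dur, rate,
                noise_rms_uau=noise_uau,
                drift_au_per_min=g.drift_au_per_min,
                temp_drift_c_per_min=g.temp_drift_c_per_min,
                seed=s, reference_intensity=g.reference_intensity,
                temperature_c=temp, phantom_id=recipe.phantom_id,
            )
            raw[profile][recipe.phantom_id] = series
            if profile == "laser":
                harm, mean = harmonize_laser(series, cfg)
            else:
                harm, mean = harmonize_ft(series, target)
            harmonized[profile][recipe.phantom_id] = harm
            means.append(mean)
        labels = design.table["glucose_mgdl"].to_numpy()
        datasets[profile] = pls.CalibrationDataset.from_spectra(means, labels)
        log.info("simulated %d phantoms for profile '%s'", len(recipes), profile)
    return StudyData(design, target, raw, harmonized, datasets)


def harmonize_laser(series: SpectralTimeSeries, cfg: RunConfig):
    """Prototype harmonization: pair-average, trim to the middle window, average.

    Returns the harmonized single-beam series (for noise benchmarking)
    and the per-phantom mean absorbance spectrum (for calibration).
    """
    pre = cfg.preprocess
    out = series
    if pre.pairwise_average:
        out = preprocess.pairwise_average(out)
    out = preprocess.trim_to_window(out, pre.trim_start_s, pre.trim_end_s)
    mean = preprocess.phantom_mean_spectrum(
        preprocess.to_absorbance(out), phantom_id=series.phantom_id
    )
    return out, mean


def harmonize_ft(series: SpectralTimeSeries, target: WavelengthGrid):
    """FT harmonization: interpolate every scan onto the laser grid, average."""
    scans = [preprocess.resample_to_grid(s, target) for s in series.scans]
    out = SpectralTimeSeries(scans, series.scan_rate, phantom_id=series.phantom_id)
    mean = preprocess.phantom_mean_spectrum(
        preprocess.to_absorbance(out), phantom_id=series.phantom_id
    )
    return out, mean


def build_calibration_dataset(
    harmonized: dict[str, SpectralTimeSeries], design: DesignTable
) -> pls.CalibrationDataset:
    """Per-phantom mean absorbance spectra + design glucose labels."""
    labels, means = [], []
    by_id = dict(zip(design.table["phantom_id"], design.table["glucose_mgdl"]))
    for pid, series in harmonized.items():
        means.append(preprocess.phantom_mean_spectrum(
            preprocess.to_absorbance(series), phantom_id=pid))
        labels.append(by_id[pid])
    return pls.CalibrationDataset.from_spectra(means, np.array(labels))


def run_benchmark(study: StudyData, cfg: RunConfig) -> dict:
    """100% line RMS-noise benchmark of the harmonized datasets.

    Reports per-profile medians/quartiles, median SNR, and the
    1/sqrt(N)-scaled one-minute equivalents.
    """
    b = cfg.benchmark
    report: dict = {"provenance": {"seed": cfg.seed, "generator": cfg.generator.__dict__}}
    for profile, series_by_pid in study.harmonized.items():
        res = noise.benchmark_dataset(series_by_pid, k=b.detrend_order,
                                      pairing=b.pairing, regressor=b.regressor)
        rate = series_by_pid[next(iter(series_by_pid))].scan_rate
        n_one_minute = rate * 60.0
        report[profile] = {
            "median_rms_uau": res.median,
            "q1_rms_uau": res.q1,
            "q3_rms_uau": res.q3,
            "n_lines": int(res.all_rms.size),
            "n_wavelengths": res.n_wavelengths,
            "median_snr": res.median_snr,
            "one_minute_rms_uau": noise.scale_rms_to_duration(res.median, n_one_minute),
            "one_minute_snr": noise.snr(
                noise.scale_rms_to_duration(res.median, n_one_minute)),
            "per_phantom_rms_uau": {p: v for p, v in res.per_phantom.items()},
        }
    return report


def run_calibrate(
    dataset: pls.CalibrationDataset,
    cfg: RunConfig,
    grid_search: bool = True,
    randomize_seed: int | None = None,
    harmonized: dict[str, SpectralTimeSeries] | None = None,
    design: DesignTable | None = None,
    inject_noise_to_uau: float | None = None,
) -> dict:
    """PLS calibration report: grid search or fixed-window LOPO CV.

    ``inject_noise_to_uau`` first calibrates a Gaussian absorbance-noise
    amplitude so the dataset's median 100% line RMS matches the target
    (requires ``harmonized`` + ``design``), then rebuilds the calibration
    dataset from the noisy spectra before fitting.
    """
    p = cfg.pls
    report: dict = {"provenance": {"seed": cfg.seed}}
    if inject_noise_to_uau is not None:
        if harmonized is None or design is None:
            raise ValueError("noise injection needs the harmonized series and design")
        sigma, achieved = noise.calibrate_injection_noise(
            harmonized, inject_noise_to_uau, seed=cfg.seed,
            k=cfg.benchmark.detrend_order)
        rng = np.random.default_rng(cfg.seed)
        noisy = {pid: noise.add_absorbance_noise(s, sigma, rng)
                 for pid, s in harmonized.items()}
        dataset = build_calibration_dataset(noisy, design)
        report["injection"] = {"sigma_au": sigma, "achieved_median_rms_uau": achieved,
                               "target_median_rms_uau": inject_noise_to_uau}
    if randomize_seed is not None:
        dataset = pls.randomize_labels(dataset, randomize_seed)
        report["randomized_labels"] = {"seed": randomize_seed}

    if grid_search:
        gs = pls.grid_search(dataset, min_width_nm=p.min_width_nm,
                             width_step_nm=p.width_step_nm,
                             start_step_nm=p.start_step_nm,
                             max_factors=p.max_factors)
        cv = pls.lopo_cv(dataset, window=gs.best_window, n_factors=gs.best_n_factors)
        report["grid_search"] = {
            "best_window_nm": list(gs.best_window),
            "best_n_factors": gs.best_n_factors,
            "best_secv_mgdl": gs.best_secv,
            "secv_vs_factors": gs.secv_vs_factors,
            "n_windows": len({(r["start_nm"], r["end_nm"]) for r in gs.records}),
        }
    else:
        cv = pls.lopo_cv(dataset, window=None, n_factors=p.n_factors)
        factors, curve = pls.lopo_cv_curve(dataset, window=None,
                                           max_factors=p.max_factors)
        report["secv_vs_factors"] = curve
    report["cv"] = {
        "secv_mgdl": cv.secv,
        "n_factors": cv.n_factors,
        "window_nm": list(cv.window),
        "predictions": {pid: {"y_ref": float(a), "y_pred": float(p_)}
                        for pid, a, p_ in zip(cv.phantom_ids, cv.actual, cv.predicted)},
    }
    report["diagnostics"] = pls.regression_diagnostics(cv)
    return report


def run_randomization_control(
    dataset: pls.CalibrationDataset,
    cfg: RunConfig,
    n_seeds: int = 20,
    window: tuple[float, float] | None = None,
    n_factors: int | None = None,
) -> dict:
    """Randomized-label LOPO SECV over many permutation seeds.

    With labels shuffled the model has no analyte signal to exploit and
    collapses to predicting the training mean, so the SECV of the optimum
    model lands near the label standard deviation (~167 mg/dL for the
    printed design).  By default each seed's SECV is taken at the
    SECV-minimizing factor count — the same model-selection rule used for
    the correct-label calibrations (adding factors only inflates the
    randomized SECV, see the SECV-vs-factor curves); pass ``n_factors``
    to pin the factor count instead.
    """
    ss = np.random.SeedSequence([cfg.seed, 97])
    seeds = [int(s) for s in ss.generate_state(n_seeds) % (2**31)]
    secvs, opt_factors = [], []
    curve_sum = None
    for s in seeds:
        shuffled = pls.randomize_labels(dataset, s)
        if n_factors is None:
            factors, curve = pls.lopo_cv_curve(shuffled, window=window,
                                               max_factors=cfg.pls.max_factors)
            secvs.append(float(curve.min()))
            opt_factors.append(int(factors[curve.argmin()]))
            curve_sum = curve if curve_sum is None else curve_sum + curve
        else:
            secvs.append(pls.lopo_cv(shuffled, window=window,
                                     n_factors=n_factors).secv)
            opt_factors.append(n_factors)
    secvs = np.array(secvs)
    out = {
        "n_seeds": n_seeds,
        "factor_selection": "fixed" if n_factors else "optimum",
        "optimum_factors": opt_factors,
        "secv_mgdl": secvs,
        "mean_secv_mgdl": float(secvs.mean()),
        "label_sd_mgdl": float(np.std(dataset.y)),
    }
    if curve_sum is not None:
        out["mean_secv_vs_factors"] = curve_sum / n_seeds
    return out


def run_simulate_to_dir(cfg: RunConfig, out_dir, profiles=("ft", "laser"),
                        write_modulation_demo: bool = True) -> Path:
    """Write a complete synthetic study (design, recipes, spectra CSVs, manifest)."""
    from .design import recipes_to_frame
    from .spectra import simulate_modulation_cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg, profiles=profiles)
    study.design.to_csv(out / "design.csv")
    recipes_to_frame(study.design.recipes()).to_csv(out / "recipes.csv", index=False)
    manifest = {"seed": cfg.seed, "profiles": list(profiles),
                "config": cfg.to_dict(), "files": []}
    for profile in profiles:
        pdir = out / profile
        pdir.mkdir(exist_ok=True)
        for pid, series in study.raw[profile].items():
            path = pdir / f"{pid}.csv"
            io.write_series_csv(series, path, sidecar={"profile": profile,
                                                       "seed": cfg.seed})
            manifest["files"].append(str(path.relative_to(out)))
    if write_modulation_demo and "laser" in profiles:
        first = next(iter(study.raw["laser"].values()))
        cycle = simulate_modulation_cycle(
            first.scans[0], dark_level=cfg.generator.dark_level,
            sample_interval_us=cfg.generator.sample_interval_us,
            noise_sd=0.01, seed=cfg.seed)
        io.write_modulation_csv(cycle, out / "modulation_demo.csv")
        manifest["files"].append("modulation_demo.csv")
    io.write_json(manifest, out / "manifest.json")
    return out
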