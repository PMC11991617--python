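"""Simulate the synthetic study: both instrument profiles, all phantoms.

Writes raw single-beam spectra (wide CSV per phantom), the design and
recipes, one demonstration modulation-cycle stream, and a manifest with
the seeds and generator parameters, under scratch/synthetic_study/ (the
raw spectra are large).  Everything downstream can also regenerate the
study in memory from the same RunConfig, so this step is optional.
"""

from pathlib import Path

from phantomnir.config import RunConfig
from phantomnir.study import run_simulate_to_dir

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "synthetic_study"


def main() -> None:
    cfg = RunConfig(seed=1)
    # a one-minute excerpt per phantom keeps the on-disk demo ~100 MB; the
    # in-memory pipeline used by steps 03-06 runs the full durations
    cfg.generator.laser_duration_s = 60.0
    cfg.generator.ft_duration_s = 60.0
    cfg.preprocess.trim_start_s = 10.0
    cfg.preprocess.trim_end_s = 50.0
    out = run_simulate_to_dir(cfg, SCRATCH)
    n_files = sum(1 for _ in out.rglob("*.csv"))
    print(f"synthetic study written to {out} ({n_files} CSV files, "
          f"one-minute excerpt per phantom)")
    print("profiles: ft (391-point grid, 8.33 scans/s), "
          "laser (112 wavelengths, 15.15 scans/s)")


if __name__ == "__main__":
    main()
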