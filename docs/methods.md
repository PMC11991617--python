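# Methods

## The measurement problem

Glucose absorbs in the NIR first-overtone (~1540–1820 nm) and
combination (~2000–2500 nm) regions, but in aqueous, scattering samples
its bands are minute perturbations riding on the water background and a
scattering-dependent baseline. The benchmarking workflow implemented
here quantifies (i) the spectral noise floor of an instrument–interface
combination, via 100% line RMS noise, and (ii) the analytical utility of
the resulting spectra, via leave-one-phantom-out PLS calibration against
a designed phantom set, with a label-randomization control for
selectivity.

## Phantom design and recipe math

The design is the full cross of 7 glucose levels (0, 82.5, 167.5, 250,
332.5, 417.5, 500 mg/dL) with 7 polystyrene-bead levels (1466, 1588,
1712, 1734, 1956, 2078, 2200 mg/dL): 49 unique phantoms, each with fixed
Triton X-100 (800), saline (966) and Germall (100 mg/dL). Two notes:

* Designs of this kind are sometimes labelled 7-level Latin hypercubes,
  but a strict Latin hypercube would use each level only once; 49 unique
  phantoms with both margins balanced implies the full 7×7 cross, so
  that is what `build_design` constructs.
* The bead spacing is irregular (1712 → 1734 rather than ~1834). The
  printed values are treated as authoritative and used verbatim.

Recipes are gravimetric (mass of stock = C·V·ρ/C_stock); dispensed
volume is taken as mass/ρ_stock, water fills the flask, and realised
concentrations are recomputed from dispensed volumes as a consistency
check. The population SD of the design's glucose values, 166.8 mg/dL, is
the yardstick for the randomization control.

## Synthetic-data generator

No phantom spectra are publicly available, so the study runs on a
forward model whose defaults define the study conditions:

* **Optical model.** Absorbance is Beer–Lambert:
  A(λ) = f_w·A_w(λ) + Σ ε_i(λ)c_i + s₀c_beads + s₁c_beads(λ−λ_mid)
  + (dA/dT)(λ)(T−T_ref). Water is a sum of broad Gaussian bands (1450,
  1940 nm and a long-wavelength shoulder); glucose has Gaussian bands at
  1590, 1730, 2100 and 2270 nm with amplitudes such that 500 mg/dL
  produces a ~100 µAU band signal — deliberately small against the water
  background so the calibration is realistically hard. Water
  displacement (f_w = 1 − Σκᵢcᵢ, κ from partial specific volumes ~0.3 to
  0.95 mL/g·10⁻⁵ per mg/dL) is the dominant glucose signature, matching
  the physics of dilute aqueous solutes. Bead scattering contributes an
  offset plus a linear-in-λ slope, which is exactly what the quadratic
  detrend of the noise benchmark is designed to remove. All band
  parameters live in `AbsorptivityLibrary`, not in code paths.
* **Wavelength grids.** The prototype's 112 laser wavelengths are
  proprietary; the default grid is 112 uniform points over 1350–2450 nm,
  covering both glucose regions. The FT profile uses 391 points over
  1330–2470 nm and is interpolated down to the laser grid during
  harmonization.
* **Acquisition.** Laser profile: 15.15 scans/s for 7 min per phantom,
  each scan expandable into a modulation cycle (200 µs on-pulse, 300 µs
  dark, 10 µs sampling). FT profile: 8.33 scans/s for 2 min. Scan count
  is floor(duration·rate).
* **Noise.** Independent Gaussian absorbance noise per scan and
  wavelength. Defaults: 667.2 µAU per raw laser scan and 327.8/√2 µAU
  per FT scan — sized so that, after the harmonization chain (pairwise
  averaging halves the laser variance; a 100% line doubles it), the
  harmonized line medians land at the benchmark levels of 667.2 and
  327.8 µAU. The FT pipeline median comes out ~10% below its nominal
  level because the 391→112 monotone-cubic interpolation attenuates
  white noise; this attenuation is a genuine property of the
  harmonization, so it is reported rather than pre-compensated.
* **Nuisance variability.** Each phantom measurement draws a thermostat
  offset (SD 0.1 °C, acting through the temperature-sensitivity curve)
  and per-component gravimetric dispensing errors (SD 0.2% relative) —
  realistic session-to-session variability that gives the spectra
  structured cross-phantom variance beyond the design factors. Slow
  drift (10⁻⁴ AU/min) and a temperature ramp (0.05 °C/min) act within
  each acquisition.

What the generator does **not** emulate: radiative transfer or Mie
scattering (the bead effect is phenomenological), laser power dynamics,
interface repositioning artifacts, and the rich uncontrolled variability
of real measurement sessions. Consequently the synthetic calibrations
are *easier* than the real ones — correct-label SECVs land near
2–3 mg/dL rather than 6–8 mg/dL — and passing tests demonstrate the
correctness of the pipeline's statistics, not the field performance of
any instrument.

## Harmonization conventions

* Demodulation uses the mean on-signal minus the mean of the 100 µs dark
  windows immediately before and after each pulse, in wavelength order.
* Pairwise averaging uses non-overlapping consecutive pairs; a trailing
  odd scan is dropped so all outputs are equal-weight. 15.15 scans/s
  becomes 7.575 (reported 7.58).
* Trimming keeps timestamps in [150 s, 270 s) of a 7-min acquisition —
  the middle two minutes.
* Interpolation is monotone piecewise-cubic Hermite (PCHIP, the standard
  "shape-preserving piecewise cubic"); extrapolation is refused.
* Absorbance uses −log₁₀(I/I₀) with a unit reference by default: any
  common reference cancels in 100% lines and is absorbed by PLS
  centering.

## Noise benchmark conventions

* 100% lines are formed from consecutive non-overlapping scan pairs
  (1,2), (3,4), … so lines are independent under white noise.
* The detrend regressor is wavelength in nm, mapped to [−1, 1] for
  conditioning (fitting against the point index is a config option).
* The RMS denominator is N−1−k verbatim (k=2 ⇒ N−3), not the more
  common N−(k+1). With the quadratic fit absorbing 3 degrees of freedom
  this makes the squared RMS an unbiased estimate of the injected noise
  variance, which the recovery tests confirm to within the median-vs-mean
  offset of a chi distribution (≈0.5%).
* Duration scaling divides by √N with fractional scan counts used as-is
  (8.33 scans/s × 60 s = 499.8). Note that scaling the single-scan
  medians 327.8 and 667.2 µAU this way gives 14.66 and 29.8 µAU, not the
  reported one-minute values of 15.0 and 33.8 µAU; the scan counts
  behind those reported values are not stated, so the discrepancy is
  flagged here and the stated 1/√N law is implemented unchanged.
* Injection calibration bisects on the added absorbance sigma with a
  frozen noise realization per evaluation, making the objective monotone
  and the search deterministic.

## PLS conventions

* The algorithm is SIMPLS (deterministic, no convergence tolerance);
  spectra are column-centered only — absorbance units are homogeneous,
  so no variance scaling. The independent NIPALS implementation in
  scikit-learn serves as a cross-check oracle in the test suite, never
  as the implementation.
* SIMPLS models are nested in the factor count: one fit per fold yields
  the whole SECV-vs-factors curve. Rank deficiency raises an error
  naming the attainable maximum; inside curve/grid evaluations the model
  saturates at the attainable rank instead.
* SECV uses denominator N exactly.
* The grid-search lattice anchors at the grid minimum: window widths 50,
  100, … nm up to the full span, starts every 50 nm, 1–20 factors.
  Windows with fewer than two wavelengths are skipped and logged. The
  optimum is the global SECV minimum; ties break toward fewer factors,
  then narrower windows, then lower start — the optimality criterion is
  simply the lowest SECV; the tie-break beyond that is this package's
  rule.
* The real-instrument optima this benchmark emulates (windows
  1551–2378 / 1401–2238 nm, 8/10 factors, SECV 6.62/7.82 mg/dL) depend
  on the proprietary laser wavelengths and the withheld spectra; they
  are reference context, not constraints, and the synthetic study's
  optima differ.

## The randomization control and factor selection

With glucose labels permuted, a selective model has nothing to fit: the
optimum model collapses to predicting the training mean, whose
leave-one-out SECV is the label SD (up to an N/(N−1) factor,
≈ 170 mg/dL here). The control therefore scores each permutation seed at
its SECV-minimizing factor count — the same model-selection rule used
everywhere else. This matters: at a *fixed* high factor count (say 8), a
cross-validated PLS actively overfits the permuted labels and its SECV
inflates well above the label SD (≈1.3×, a direct consequence of
leave-one-out variance inflation with y-adaptive components). The
SECV-vs-factor curves make the distinction visible: falling-then-flat
under correct labels, rising under permuted ones. A fixed-factor mode
remains available via `run_randomization_control(..., n_factors=...)`.

## Problem sizes

Default study conditions (49 phantoms; laser 7 min at 15.15 scans/s, FT
2 min at 8.33 scans/s) run the full analysis drivers in tens of seconds
to ~1 min each. The test suite exercises the same code paths on scaled
acquisitions (seconds of data, sparser FT grids) chosen so the whole
suite completes in a few minutes; noise-recovery checks use ≥500 lines,
where the median RMS estimator's sampling error is ~0.5%, comfortably
inside the 3% acceptance band.

## Known limitations

* The absorptivity library is synthetic; band positions follow NIR
  chemistry but amplitudes are package choices.
* The modulation-cycle simulator uses ideal rectangular pulses; no
  laser settling, jitter or 1/f behaviour.
* Scan timestamps are idealized (uniform); the harmonization assumes no
  dropped scans.
* The grid search is exhaustive over contiguous windows only; no
  discontinuous variable selection.
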