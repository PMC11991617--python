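"""Partial least squares calibration with leave-one-phantom-out validation.

The calibration workflow mirrors standard NIR chemometrics practice:

* spectra (absorbance, one mean spectrum per phantom) are column-centered
  — no variance scaling, since absorbance units are homogeneous;
* a SIMPLS decomposition (de Jong 1993) extracts latent variables; the
  algorithm is deterministic and yields nested models, so coefficients
  for every factor count up to the maximum come from a single fit;
* performance is summarised by the standard error of cross-validation
  over leave-one-phantom-out folds,

      SECV = sqrt( Σ_i (y_i − ŷ_i)² / N ),

  with denominator N exactly;
* the wavelength window and factor count are chosen by exhaustive grid
  search over contiguous windows on a 50 nm lattice and 1–20 factors,
  taking the minimum SECV (ties: fewer factors, then narrower window,
  then lower start);
* selectivity is probed by refitting after randomly permuting the
  glucose labels — a model with no analyte signal collapses to predicting
  the mean, so its SECV approaches the label standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import AbsorbanceSpectrum
from .spectra import WavelengthGrid

__all__ = [
    "CalibrationDataset",
    "PLSModel",
    "CVResult",
    "GridSearchResult",
    "fit_pls",
    "predict",
    "secv",
    "lopo_cv",
    "lopo_cv_curve",
    "grid_search",
    "regression_diagnostics",
    "randomize_labels",
]

log = logging.getLogger(__name__)


@dataclass
class CalibrationDataset:
    """Phantom mean spectra (rows) with glucose reference labels."""

    X: np.ndarray  # phantoms x wavelengths, AU
    y: np.ndarray  # glucose, mg/dL
    phantom_ids: list[str]
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (phantoms x wavelengths)")
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.phantom_ids):
            raise ValueError("rows of X, labels and phantom ids must align")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("columns of X must match the wavelength grid")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")

    @classmethod
    def from_spectra(cls, spectra: list[AbsorbanceSpectrum],
                     labels: np.ndarray) -> "CalibrationDataset":
        grid = spectra[0].grid
        X = np.vstack([s.values for s in spectra])
        ids = [s.phantom_id or f"phantom{i:02d}" for i, s in enumerate(spectra)]
        return cls(X, np.asarray(labels, float), ids, grid)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def window_indices(self, start_nm: float, end_nm: float) -> np.ndarray:
        """Indices of wavelengths with start_nm <= λ <= end_nm."""
        wl = self.grid.wavelengths
        return np.flatnonzero((wl >= start_nm) & (wl <= end_nm))

    def subset_rows(self, rows: np.ndarray) -> "CalibrationDataset":
        return CalibrationDataset(self.X[rows], self.y[rows],
                                  [self.phantom_ids[i] for i in rows], self.grid)


@dataclass
class PLSModel:
    """A fitted SIMPLS model; prediction is affine in the input spectrum."""

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A matrix R of x-weights (normalised scores)
    y_loadings: np.ndarray  # length-A vector q
    window: tuple[float, float]  # nm range of the training window
    column_idx: np.ndarray  # indices into the full grid

    def coefficients(self, n_factors: int | None = None) -> np.ndarray:
        """Regression vector b such that ŷ = ȳ + (x − x̄)·b (nested in factors)."""
        a = self.n_factors if n_factors is None else n_factors
        if not 1 <= a <= self.n_factors:
            raise ValueError(f"n_factors must be in [1, {self.n_factors}]")
        return self.weights[:, :a] @ self.y_loadings[:a]


@dataclass
class CVResult:
    """Leave-one-phantom-out predictions and their SECV."""

    phantom_ids: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    secv: float
    n_factors: int
    window: tuple[float, float]


@dataclass
class GridSearchResult:
    """SECV surface over (window, factor count) and the selected optimum."""

    records: list[dict]  # start_nm, end_nm, n_factors, secv_mgdl
    best_window: tuple[float, float]
    best_n_factors: int
    best_secv: float
    secv_vs_factors: np.ndarray = field(default=None)  # at the optimal window

    def surface(self) -> np.ndarray:
        return np.array([(r["start_nm"], r["end_nm"], r["n_factors"], r["secv_mgdl"])
                         for r in self.records])


def _simpls(Xc: np.ndarray, yc: np.ndarray, n_factors: int,
            strict: bool = True) -> tuple[np.ndarray, np.ndarray, int]:
    """SIMPLS for a univariate response on pre-centered data.

    Returns (R, q, n_attained): R holds x-weight vectors scaled so scores
    t = Xc R are orthonormal; q the y-loadings.  The regression vector
    for k factors is R[:, :k] @ q[:k].  When the data rank (or the
    residual x–y covariance) is exhausted before ``n_factors``, raises if
    ``strict`` else returns the attainable truncation.
    """
    n, p = Xc.shape
    s = Xc.T @ yc  # p-vector (univariate y: the dominant direction is s itself)
    R = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    V = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    t1_norm = None
    for a in range(n_factors):
        r = s.copy()
        t = Xc @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        # rank tolerance relative to the leading factor's score norm
        if normt <= (1e-12 if t1_norm is None else 1e-12 * t1_norm):
            if strict:
                raise np.linalg.LinAlgError(
                    f"rank deficiency: only {a} PLS factor(s) attainable "
                    f"(requested {n_factors})"
                )
            return R[:, :a], q[:a], a
        if t1_norm is None:
            t1_norm = normt
        t /= normt
        r /= normt
        p_load = Xc.T @ t
        q[a] = yc @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], T[:, a], V[:, a] = r, t, v
    return R, q, n_factors


def fit_pls(
    dataset: CalibrationDataset,
    n_factors: int,
    window: tuple[float, float] | None = None,
    strict: bool = True,
) -> PLSModel:
    """Fit a SIMPLS calibration on (optionally window-restricted) spectra.

    Spectra are column-centered and the label mean-centered; no scaling.
    With ``strict`` (default) a rank-deficient fit raises, reporting the
    attainable maximum; otherwise the model is truncated to the rank.
    """
    if window is None:
        idx = np.arange(dataset.X.shape[1])
        window = dataset.grid.span
    else:
        idx = dataset.window_indices(*window)
        if idx.size < 2:
            raise ValueError(f"window {window} nm contains fewer than 2 wavelengths")
    X = dataset.X[:, idx]
    max_f = min(dataset.n - 1, idx.size)
    if not 1 <= n_factors <= max_f:
        raise ValueError(
            f"n_factors must be in [1, {max_f}] for {dataset.n} phantoms and "
            f"{idx.size} wavelengths; got {n_factors}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(dataset.y.mean())
    R, q, attained = _simpls(X - x_mean, dataset.y - y_mean, n_factors, strict=strict)
    return PLSModel(attained, x_mean, y_mean, R, q, window, idx)


def predict(model: PLSModel, spectrum: np.ndarray | AbsorbanceSpectrum,
            n_factors: int | None = None) -> float | np.ndarray:
    """Predict glucose (mg/dL) for one spectrum or a matrix of spectra."""
    x = spectrum.values if isinstance(spectrum, AbsorbanceSpectrum) else np.asarray(spectrum, float)
    x = x[..., model.column_idx] if x.shape[-1] != model.column_idx.size else x
    b = model.coefficients(n_factors)
    out = model.y_mean + (x - model.x_mean) @ b
    return float(out) if np.ndim(out) == 0 else out


def secv(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Standard error of cross-validation: sqrt(Σ(y−ŷ)²/N), denominator N."""
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def lopo_cv(
    dataset: CalibrationDataset,
    window: tuple[float, float] | None = None,
    n_factors: int = 8,
) -> CVResult:
    """Leave-one-phantom-out cross-validation at a fixed factor count."""
    preds = np.empty(dataset.n)
    for i in range(dataset.n):
        keep = np.setdiff1d(np.arange(dataset.n), [i])
        model = fit_pls(dataset.subset_rows(keep), n_factors, window=window)
        preds[i] = predict(model, dataset.X[i])
    win = window if window is not None else dataset.grid.span
    return CVResult(list(dataset.phantom_ids), dataset.y.copy(), preds,
                    secv(dataset.y, preds), n_factors, win)


def lopo_cv_curve(
    dataset: CalibrationDataset,
    window: tuple[float, float] | None = None,
    max_factors: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """SECV for every factor count 1..max_factors (one nested fit per fold).

    Returns ``(factors, secv_values)``.  ``max_factors`` is clipped to the
    rank bound of the leave-one-out training sets.
    """
    idx = (np.arange(dataset.X.shape[1]) if window is None
           else dataset.window_indices(*window))
    if idx.size < 2:
        raise ValueError(f"window {window} nm contains fewer than 2 wavelengths")
    a_max = min(max_factors, dataset.n - 2, idx.size)
    preds = np.empty((dataset.n, a_max))
    for i in range(dataset.n):
        keep = np.setdiff1d(np.arange(dataset.n), [i])
        model = fit_pls(dataset.subset_rows(keep), a_max,
                        window=window if window is not None else None,
                        strict=False)
        for a in range(1, a_max + 1):
            # beyond the attainable rank the model saturates
            preds[i, a - 1] = predict(model, dataset.X[i],
                                      n_factors=min(a, model.n_factors))
    factors = np.arange(1, a_max + 1)
    curves = np.array([secv(dataset.y, preds[:, a - 1]) for a in factors])
    return factors, curves


def _window_lattice(span: tuple[float, float], min_width: float,
                    width_step: float, start_step: float) -> list[tuple[float, float]]:
    lo, hi = span
    full = hi - lo
    windows = []
    width = min_width
    while width <= full + 1e-9:
        start = lo
        while start + width <= hi + 1e-9:
            windows.append((start, min(start + width, hi)))
            start += start_step
        width += width_step
    if not any(abs(w[0] - lo) < 1e-9 and abs(w[1] - hi) < 1e-9 for w in windows):
        windows.append((lo, hi))
    return windows


def grid_search(
    dataset: CalibrationDataset,
    min_width_nm: float = 50.0,
    width_step_nm: float = 50.0,
    start_step_nm: float = 50.0,
    max_factors: int = 20,
) -> GridSearchResult:
    """Exhaustive SECV surface over contiguous wavelength windows and factors.

    Windows lie on a lattice anchored at the grid minimum: widths
    min_width, min_width+step, ... up to the full span, starts every
    ``start_step_nm``.  Each window maps to the wavelengths it contains;
    windows with fewer than 2 wavelengths are skipped (logged).  The
    optimum is the global SECV minimum; ties break toward fewer factors,
    then narrower windows, then lower start.
    """
    span = dataset.grid.span
    if span[1] - span[0] < min_width_nm:
        raise ValueError("dataset wavelength span is narrower than the minimum window")
    records: list[dict] = []
    best = None  # (secv, n_factors, width, start)
    for start, end in _window_lattice(span, min_width_nm, width_step_nm, start_step_nm):
        idx = dataset.window_indices(start, end)
        if idx.size < 2:
            log.info("skipping window %.0f–%.0f nm: %d wavelength(s)", start, end, idx.size)
            continue
        factors, curves = lopo_cv_curve(dataset, window=(start, end),
                                        max_factors=max_factors)
        for a, s in zip(factors, curves):
            records.append({"start_nm": start, "end_nm": end,
                            "n_factors": int(a), "secv_mgdl": float(s)})
            key = (float(s), int(a), end - start, start)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no feasible window on the search lattice")
    best_secv, best_a, best_width, best_start = best
    best_window = (best_start, best_start + best_width)
    _, curve = lopo_cv_curve(dataset, window=best_window, max_factors=max_factors)
    return GridSearchResult(records, best_window, best_a, best_secv,
                            secv_vs_factors=curve)


def regression_diagnostics(cv: CVResult) -> dict:
    """OLS of predicted on reference: slope, intercept (with SEs) and R²."""
    res = stats.linregress(cv.actual, cv.predicted)
    return {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "intercept": float(res.intercept),
        "intercept_se": float(res.intercept_stderr),
        "r_squared": float(res.rvalue**2),
    }


def randomize_labels(dataset: CalibrationDataset, seed: int) -> CalibrationDataset:
    """Permute glucose labels uniformly at random (multiset preserved)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n)
    return CalibrationDataset(dataset.X.copy(), dataset.y[perm],
                              list(dataset.phantom_ids), dataset.grid)
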