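"""NIR preprocessing and PLSR calibration against NMR references.

The FT-NIR spectra (4000-12000 cm^-1, 2074 points) carry strong
absorption/noise above 8975 cm^-1 in coloured product solutions and
detector noise below 4611 cm^-1, so quantitative work restricts to the
central window.  Preprocessing is a short ordered pipeline per analyte
— range selection, standard normal variate (SNV), polynomial or offset
baselines — followed by partial least squares regression with an
analyte-specific factor count.  Validation follows the three-way
scheme: random 20-segment cross-validation, systematic (leave-one-run-
out) cross-validation, and prediction of a held-out run.

Default per-analyte configurations (factor counts 1/3/5/4 for aniline,
o-FNB, Li-NDPA, Li-aniline) live in :data:`DEFAULT_ANALYTE_CONFIG`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .spectra import Spectrum

__all__ = [
    "PreprocessSpec",
    "PLSRModel",
    "ValidationReport",
    "snv",
    "poly_baseline",
    "select_range",
    "apply_preprocess",
    "fit_plsr",
    "cross_validate",
    "evaluate_test",
    "DEFAULT_ANALYTE_CONFIG",
]

#: central working window deemed feasible for quantitative analysis
WORK_RANGE = (4611.0, 8957.0)

#: default seed for the random CV segment shuffle
DEFAULT_CV_SEED = 20171017


def snv(x: np.ndarray | Spectrum) -> np.ndarray | Spectrum:
    """Standard normal variate: per-spectrum (x - mean) / sd, sample SD.

    Removes multiplicative scatter (gain) and additive offsets.  Raises
    on zero-variance input.  Accepts a single spectrum, a 1-D array, or
    a 2-D matrix (rows = spectra).
    """
    if isinstance(x, Spectrum):
        return x.copy(intensity=snv(x.intensity))
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        sd = arr.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance spectrum: SNV undefined")
        return (arr - arr.mean()) / sd
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance spectrum: SNV undefined")
    return (arr - arr.mean(axis=1, keepdims=True)) / sd


def select_range(axis: np.ndarray, X: np.ndarray, lo: float, hi: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Restrict spectra to the closed wavenumber window [lo, hi]."""
    lo, hi = min(lo, hi), max(lo, hi)
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"range [{lo}, {hi}] selects no points")
    X = np.asarray(X, float)
    return axis[mask], (X[..., mask] if X.ndim > 1 else X[mask])


def poly_baseline(spec: Spectrum | tuple[np.ndarray, np.ndarray],
                  window: tuple[float, float], order: int,
                  support_frac: float = 0.15) -> Spectrum | np.ndarray:
    """Restrict to ``window`` and subtract a least-squares polynomial of
    the given order fitted to the window's endpoint support regions
    (outer ``support_frac`` of points on each side), where the baseline
    is visible and the analyte band is not.  Order 0 subtracts the
    support mean."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if isinstance(spec, Spectrum):
        sub = spec.crop(*window)
        corrected = poly_baseline((sub.axis, sub.intensity), window, order,
                                  support_frac)
        return Spectrum(sub.axis, corrected, dict(sub.meta))
    axis, y = spec
    axis = np.asarray(axis, float)
    y = np.asarray(y, float)
    if axis.size < order + 2:
        raise ValueError("too few points in window for requested order")
    k = max(int(support_frac * axis.size), (order + 2 + 1) // 2, 2)
    support = np.zeros(axis.size, dtype=bool)
    support[:k] = True
    support[-k:] = True
    ax = axis - axis.mean()
    coeffs = np.polyfit(ax[support], y[support], order)
    return y - np.polyval(coeffs, ax)


@dataclass
class PreprocessSpec:
    """Ordered preprocessing pipeline for one analyte.

    ``steps`` entries: ``("select_range", lo, hi)``, ``("snv",)``,
    ``("poly_baseline", lo, hi, order)``, ``("offset_baseline", lo, hi)``.
    """

    steps: list[tuple] = field(default_factory=lambda: [
        ("select_range", *WORK_RANGE), ("snv",)])

    def apply(self, axis: np.ndarray, X: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, float))
        for step in self.steps:
            kind = step[0]
            if kind == "select_range":
                axis, X = select_range(axis, X, step[1], step[2])
            elif kind == "snv":
                X = snv(X)
            elif kind in ("poly_baseline", "offset_baseline"):
                lo, hi = step[1], step[2]
                order = step[3] if kind == "poly_baseline" else 0
                mask = (axis >= min(lo, hi)) & (axis <= max(lo, hi))
                sub_axis = axis[mask]
                X = np.vstack([
                    poly_baseline((sub_axis, row[mask]), (lo, hi), order)
                    for row in X])
                axis = sub_axis
            else:
                raise ValueError(f"unknown preprocessing step '{kind}'")
        return axis, X


def apply_preprocess(spec: PreprocessSpec, axis: np.ndarray, X: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    return spec.apply(axis, X)


#: per-analyte defaults: preprocessing + factor count
DEFAULT_ANALYTE_CONFIG: dict[str, dict] = {
    "aniline": {
        "n_factors": 1,
        "preprocess": PreprocessSpec([("select_range", *WORK_RANGE), ("snv",),
                                      ("poly_baseline", 5500.0, 6100.0, 2)]),
    },
    "oFNB": {
        "n_factors": 3,
        "preprocess": PreprocessSpec([("poly_baseline", 5995.0, 6307.0, 3)]),
    },
    "LiNDPA": {
        "n_factors": 5,
        "preprocess": PreprocessSpec([("select_range", *WORK_RANGE), ("snv",)]),
    },
    "Lianiline": {
        "n_factors": 4,
        "preprocess": PreprocessSpec([("select_range", *WORK_RANGE), ("snv",),
                                      ("offset_baseline", 6500.0, 7400.0)]),
    },
}


@dataclass
class PLSRModel:
    """A fitted PLSR calibration for one analyte (mol/L in, mol/L out)."""

    analyte: str
    n_factors: int
    preprocess: PreprocessSpec
    axis: np.ndarray
    _pls: PLSRegression = field(repr=False, default=None)

    def predict_matrix(self, Xp: np.ndarray) -> np.ndarray:
        """Predict from already-preprocessed spectra."""
        return self._pls.predict(np.atleast_2d(Xp)).ravel()

    def predict(self, axis: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Preprocess raw spectra then predict."""
        _, Xp = self.preprocess.apply(axis, X)
        return self.predict_matrix(Xp)


@dataclass
class ValidationReport:
    """RMSE summary in mmol/L, matching the reporting convention."""

    analyte: str
    n_factors: int
    rmse_cv_random: float | None = None
    rmse_cv_systematic: float | None = None
    rmse_test: float | None = None
    rmsecv_curve: dict[int, float] = field(default_factory=dict)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_factors: int,
             analyte: str = "", preprocess: PreprocessSpec | None = None,
             axis: np.ndarray | None = None) -> PLSRModel:
    """Fit a mean-centred NIPALS PLSR on preprocessed spectra ``X``.

    ``X`` rows are samples; ``y`` the NMR reference concentrations in
    mol/L.  ``n_factors`` is truncated (with a warning) if it exceeds
    what the data can support.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows must match len(y)")
    if X.shape[0] < n_factors + 1:
        raise ValueError("need at least n_factors + 1 samples")
    max_rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = n_factors
    if y.std() == 0.0:
        # degenerate but legal: constant target -> intercept-only model
        k = 1
    elif k > max(max_rank, 1):
        import warnings
        warnings.warn(f"n_factors={n_factors} exceeds rank {max_rank}; truncated")
        k = max(max_rank, 1)
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    return PLSRModel(analyte=analyte, n_factors=k,
                     preprocess=preprocess or PreprocessSpec(steps=[]),
                     axis=axis if axis is not None else np.arange(X.shape[1]),
                     _pls=pls)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def cross_validate(X: np.ndarray, y: np.ndarray, scheme: dict,
                   n_factors_grid: list[int]) -> dict[int, float]:
    """RMSECV (mmol/L) per factor count under the given CV scheme.

    ``scheme`` is ``{"random_segments": 20, "seed": s}`` (seeded shuffle
    into near-equal segments) or ``{"systematic": run_labels}`` (leave
    one run out per fold).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    folds: list[np.ndarray] = []
    if "random_segments" in scheme:
        k = int(scheme["random_segments"])
        if k > n:
            raise ValueError("segment count exceeds sample count")
        rng = np.random.default_rng(scheme.get("seed", DEFAULT_CV_SEED))
        perm = rng.permutation(n)
        folds = [np.sort(f) for f in np.array_split(perm, k)]
    elif "systematic" in scheme:
        labels = np.asarray(scheme["systematic"])
        uniq = np.unique(labels)
        if uniq.size < 2:
            raise ValueError("systematic CV needs >= 2 distinct run labels")
        folds = [np.flatnonzero(labels == u) for u in uniq]
    else:
        raise ValueError("scheme must contain 'random_segments' or 'systematic'")

    out: dict[int, float] = {}
    for nf in n_factors_grid:
        sq_err = np.empty(n)
        for hold in folds:
            train = np.setdiff1d(np.arange(n), hold)
            if train.size < nf + 1:
                continue
            model = fit_plsr(X[train], y[train], nf)
            sq_err[hold] = (model.predict_matrix(X[hold]) - y[hold]) ** 2
        out[nf] = float(np.sqrt(np.mean(sq_err))) * 1000.0  # mmol/L
    return out


def evaluate_test(model: PLSRModel, X_test: np.ndarray, y_test: np.ndarray,
                  preprocessed: bool = True) -> float:
    """Test-set RMSE in mmol/L; also usable for parity-plot export."""
    y_test = np.asarray(y_test, float).ravel()
    if y_test.size == 0:
        raise ValueError("empty test set")
    if preprocessed:
        pred = model.predict_matrix(X_test)
    else:
        pred = model.predict(model.axis, X_test)
    return _rmse(pred, y_test) * 1000.0
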