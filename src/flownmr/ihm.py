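"""Indirect Hard Modeling (IHM) of low-field NMR spectra.

At 43 MHz the proton multiplets of the lithiation mixture overlap, so
individual peak integrals are not directly accessible.  IHM instead
fits a constrained superposition of parametric pure-component models
(sums of pseudo-Voigt peaks) to the mixture spectrum.  During the
mixture fit each component may scale in intensity, shift globally (and
slightly per peak) and scale its linewidths, but the *area ratios*
between the peaks of one component are held exactly fixed — the
physical plausibility constraint that makes the fitted component areas
meaningful.

Absolute concentrations then follow from a one-point calibration: a
single stream of known concentration fixes the conversion factor xi in

    c_i = xi * A_i / nu_i

where ``A_i`` is the fitted absolute integral of component ``i`` and
``nu_i`` its number of contributing protons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

from .spectra import Spectrum

__all__ = [
    "PseudoVoigtPeak",
    "ModelConstraints",
    "PureComponentModel",
    "MixtureFitResult",
    "CalibrationFactor",
    "pseudo_voigt",
    "fit_pure_component",
    "fit_mixture",
    "calibrate_xi",
    "quantify",
    "load_model",
    "save_model",
    "load_model_library",
]

_GAUSS_AREA = 0.5 * np.sqrt(np.pi / np.log(2.0))  # unit-height, unit-FWHM
_LORENTZ_AREA = np.pi / 2.0


def pseudo_voigt(x: np.ndarray, position: float, height: float,
                 fwhm: float, gauss_fraction: float) -> np.ndarray:
    """eta*Gaussian + (1-eta)*Lorentzian sharing position and FWHM."""
    dx = (x - position) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * dx * dx)
    lorentz = 1.0 / (1.0 + 4.0 * dx * dx)
    return height * (gauss_fraction * gauss + (1.0 - gauss_fraction) * lorentz)


@dataclass
class PseudoVoigtPeak:
    """One basic peak function of a pure-component model."""

    position: float          # ppm
    height: float
    fwhm: float              # ppm
    gauss_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.height < 0:
            raise ValueError("height must be non-negative")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")

    @property
    def area(self) -> float:
        """Analytic integral of the peak."""
        return self.height * self.fwhm * (
            self.gauss_fraction * _GAUSS_AREA
            + (1.0 - self.gauss_fraction) * _LORENTZ_AREA)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return pseudo_voigt(x, self.position, self.height, self.fwhm,
                            self.gauss_fraction)


@dataclass
class ModelConstraints:
    """Bounds on how a component model may deform during a mixture fit.

    Defaults are tight enough to preserve identifiability on 43-MHz
    linewidths: ±0.05 ppm global shift, ±0.01 ppm per-peak shift, and
    width scaling within [0.8, 1.25].
    """

    global_shift: float = 0.05
    peak_shift: float = 0.01
    width_scale_lo: float = 0.8
    width_scale_hi: float = 1.25


@dataclass
class PureComponentModel:
    """A named analyte as a frozen sum of pseudo-Voigt peaks.

    ``relative_areas`` are frozen when the model is built and are never
    adjusted by the mixture fit.  ``nu`` is the number of protons the
    modelled signals represent, used by the quantification integral.
    """

    name: str
    peaks: list[PseudoVoigtPeak]
    nu: int
    constraints: ModelConstraints = field(default_factory=ModelConstraints)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("model needs at least one peak")
        if int(self.nu) < 1:
            raise ValueError("nu must be a positive integer")
        self.nu = int(self.nu)

    @property
    def reference_area(self) -> float:
        """Total analytic area of the model at unit weight."""
        return float(sum(p.area for p in self.peaks))

    @property
    def relative_areas(self) -> np.ndarray:
        areas = np.array([p.area for p in self.peaks])
        return areas / areas.sum()

    def evaluate(self, x: np.ndarray, weight: float = 1.0,
                 global_shift: float = 0.0, width_scale: float = 1.0,
                 peak_shifts: np.ndarray | None = None) -> np.ndarray:
        """Deformed component signal.

        A single width scale per component preserves the intra-component
        area ratios exactly (every peak area scales by the same factor).
        """
        if peak_shifts is None:
            peak_shifts = np.zeros(len(self.peaks))
        out = np.zeros_like(x, dtype=float)
        for pk, ps in zip(self.peaks, peak_shifts):
            out += pseudo_voigt(x, pk.position + global_shift + ps,
                                pk.height, pk.fwhm * width_scale,
                                pk.gauss_fraction)
        return weight * out


@dataclass
class MixtureFitResult:
    """Outcome of fitting a superposition of component models."""

    component_names: list[str]
    weights: np.ndarray              # per-component area scale (incl. width scale)
    areas: np.ndarray                # absolute integrals A_i
    global_shifts: np.ndarray
    width_scales: np.ndarray
    peak_shifts: dict[str, np.ndarray]
    baseline_coeffs: np.ndarray
    residual_norm: float

    def area(self, name: str) -> float:
        return float(self.areas[self.component_names.index(name)])


@dataclass
class CalibrationFactor:
    """Concentration conversion factor xi in (mol/L) per (area/nucleus)."""

    xi: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")


def calibrate_xi(area: float, nu: int, known_conc: float,
                 source: str = "") -> CalibrationFactor:
    """One-point calibration: invert c = xi * A / nu for xi."""
    if area <= 0 or nu < 1 or known_conc <= 0:
        raise ValueError("area, nu and known_conc must be positive")
    return CalibrationFactor(xi=known_conc * nu / area, source=source)


def quantify(fit: MixtureFitResult, xi: CalibrationFactor,
             nu_map: dict[str, int]) -> dict[str, float]:
    """Convert fitted areas to molar concentrations, c_i = xi * A_i / nu_i."""
    out: dict[str, float] = {}
    for name, area in zip(fit.component_names, fit.areas):
        if name not in nu_map:
            raise KeyError(f"no proton count (nu) configured for '{name}'")
        out[name] = xi.xi * float(area) / nu_map[name]
    return out


# ---------------------------------------------------------------------------
# pure-component model building


def fit_pure_component(spec: Spectrum, n_peaks: int, nu: int = 1,
                       name: str = "component",
                       init_positions: list[float] | None = None,
                       constraints: ModelConstraints | None = None,
                       ) -> PureComponentModel:
    """Fit ``n_peaks`` pseudo-Voigt peaks + a linear baseline to a
    pure-analyte spectrum and freeze the result into a component model."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    x, y = spec.axis, spec.intensity
    ymax = float(np.max(np.abs(y)))
    if ymax == 0 or float(np.std(y)) == 0.0:
        raise ValueError("flat/zero spectrum: nothing to model")

    if init_positions is None:
        # greedy peak picking on a smoothed copy
        work = y.copy()
        span = x[-1] - x[0]
        init_positions = []
        for _ in range(n_peaks):
            i = int(np.argmax(work))
            init_positions.append(float(x[i]))
            half = max(int(0.02 * len(x)), 3)
            work[max(i - half, 0): i + half] = -np.inf
        init_positions.sort()
    if len(init_positions) != n_peaks:
        raise ValueError("init_positions length must equal n_peaks")

    w0 = 0.01 * (x[-1] - x[0])
    p0, lo, hi = [], [], []
    for pos in init_positions:
        p0 += [pos, ymax * 0.5, w0, 0.5]
        lo += [x[0], 0.0, (x[1] - x[0]) * 0.5, 0.0]
        hi += [x[-1], 5.0 * ymax, (x[-1] - x[0]) * 0.5, 1.0]
    p0 += [0.0, 0.0]               # linear baseline
    lo += [-np.inf, -np.inf]
    hi += [np.inf, np.inf]

    def resid(p: np.ndarray) -> np.ndarray:
        model = p[-2] + p[-1] * (x - x.mean())
        for k in range(n_peaks):
            pos, h, w, eta = p[4 * k: 4 * k + 4]
            model = model + pseudo_voigt(x, pos, h, w, eta)
        return model - y

    sol = least_squares(resid, np.asarray(p0), bounds=(np.asarray(lo), np.asarray(hi)),
                        method="trf", max_nfev=20000)
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if not sol.success and r2 < 0.99:
        raise RuntimeError(
            f"pure-component fit did not converge (R^2={r2:.4f}, "
            f"residual={ss_res:.3g})")
    peaks = []
    for k in range(n_peaks):
        pos, h, w, eta = sol.x[4 * k: 4 * k + 4]
        peaks.append(PseudoVoigtPeak(float(pos), float(h), float(w), float(eta)))
    peaks.sort(key=lambda p: p.position)
    return PureComponentModel(name=name, peaks=peaks, nu=nu,
                              constraints=constraints or ModelConstraints())


# ---------------------------------------------------------------------------
# mixture fitting


def _pack_bounds(models: list[PureComponentModel], per_peak_shifts: bool,
                 baseline_order: int, scale: float):
    """Initial point and bounds: per component (weight, gshift, wscale)
    then optional per-peak shifts, then baseline coefficients."""
    p0, lo, hi = [], [], []
    for m in models:
        c = m.constraints
        p0 += [0.5 * scale, 0.0, 1.0]
        lo += [0.0, -c.global_shift, c.width_scale_lo]
        hi += [np.inf, c.global_shift, c.width_scale_hi]
    if per_peak_shifts:
        for m in models:
            c = m.constraints
            p0 += [0.0] * len(m.peaks)
            lo += [-c.peak_shift] * len(m.peaks)
            hi += [c.peak_shift] * len(m.peaks)
    p0 += [0.0] * (baseline_order + 1)
    lo += [-np.inf] * (baseline_order + 1)
    hi += [np.inf] * (baseline_order + 1)
    return np.asarray(p0), np.asarray(lo), np.asarray(hi)


def fit_mixture(spec: Spectrum, models: list[PureComponentModel],
                baseline_order: int = 2, per_peak_shifts: bool = True,
                n_starts: int = 3, x0: np.ndarray | None = None,
                seed: int = 0) -> MixtureFitResult:
    """Fit the constrained superposition of component models to a
    mixture spectrum.

    Free parameters per component: an intensity weight (>= 0, so an
    absent component pins at zero), a bounded global ppm shift and a
    bounded common width-scale factor; optionally a small bounded shift
    per peak.  A polynomial baseline (default order 2) is fitted
    jointly.  Intra-component relative areas are preserved exactly by
    construction.  ``x0`` warm-starts the optimizer (used when
    quantifying a time series spectrum-by-spectrum); otherwise up to
    ``n_starts`` jittered starts are tried and the best residual wins.
    """
    if not models:
        raise ValueError("need at least one component model")
    x, y = spec.axis, spec.intensity
    for m in models:
        positions = [p.position for p in m.peaks]
        if min(positions) < x[0] or max(positions) > x[-1]:
            raise ValueError(f"model '{m.name}' has peaks outside the axis range")

    scale = float(np.max(np.abs(y))) or 1.0
    heights_max = max(max(p.height for p in m.peaks) for m in models)
    scale = scale / heights_max if heights_max > 0 else scale
    p0, lo, hi = _pack_bounds(models, per_peak_shifts, baseline_order, scale)
    n_comp = len(models)
    ax_c = x - x.mean()

    def unpack(p: np.ndarray):
        comp = p[: 3 * n_comp].reshape(n_comp, 3)
        off = 3 * n_comp
        pshifts = []
        if per_peak_shifts:
            for m in models:
                k = len(m.peaks)
                pshifts.append(p[off: off + k])
                off += k
        else:
            pshifts = [np.zeros(len(m.peaks)) for m in models]
        bl = p[off:]
        return comp, pshifts, bl

    def resid(p: np.ndarray) -> np.ndarray:
        comp, pshifts, bl = unpack(p)
        model = np.polyval(bl, ax_c)
        for m, (w, gs, ws), ps in zip(models, comp, pshifts):
            model = model + m.evaluate(x, w, gs, ws, ps)
        return model - y

    rng = np.random.default_rng(seed)
    starts = [p0]
    if x0 is not None:
        starts = [np.clip(np.asarray(x0, float), lo, hi)]
    else:
        for _ in range(max(n_starts - 1, 0)):
            jit = p0.copy()
            jit[1: 3 * n_comp: 3] += rng.uniform(-0.01, 0.01, n_comp)
            jit[1: 3 * n_comp: 3] = np.clip(jit[1: 3 * n_comp: 3],
                                            lo[1: 3 * n_comp: 3],
                                            hi[1: 3 * n_comp: 3])
            starts.append(jit)

    best = None
    for s in starts:
        sol = least_squares(resid, s, bounds=(lo, hi), method="trf",
                            max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18 * max(float(np.sum(y ** 2)), 1.0):
            break

    comp, pshifts, bl = unpack(best.x)
    weights = comp[:, 0] * comp[:, 2]          # width scale rescales every area
    areas = np.array([w * m.reference_area for w, m in zip(weights, models)])
    return MixtureFitResult(
        component_names=[m.name for m in models],
        weights=weights,
        areas=areas,
        global_shifts=comp[:, 1].copy(),
        width_scales=comp[:, 2].copy(),
        peak_shifts={m.name: np.asarray(ps) for m, ps in zip(models, pshifts)},
        baseline_coeffs=np.asarray(bl),
        residual_norm=float(2.0 * best.cost),
    )


# ---------------------------------------------------------------------------
# model library persistence (the "model database": one YAML file per analyte)


def save_model(model: PureComponentModel, path: str | Path) -> None:
    doc = {
        "schema": 1,
        "name": model.name,
        "nu": int(model.nu),
        "peaks": [
            {"position": float(p.position), "height": float(p.height),
             "fwhm": float(p.fwhm), "gauss_fraction": float(p.gauss_fraction)}
            for p in model.peaks
        ],
        "constraints": {
            "global_shift": model.constraints.global_shift,
            "peak_shift": model.constraints.peak_shift,
            "width_scale_lo": model.constraints.width_scale_lo,
            "width_scale_hi": model.constraints.width_scale_hi,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> PureComponentModel:
    doc = yaml.safe_load(Path(path).read_text())
    cons = doc.get("constraints", {})
    return PureComponentModel(
        name=doc["name"],
        nu=int(doc["nu"]),
        peaks=[PseudoVoigtPeak(**p) for p in doc["peaks"]],
        constraints=ModelConstraints(
            global_shift=cons.get("global_shift", 0.05),
            peak_shift=cons.get("peak_shift", 0.01),
            width_scale_lo=cons.get("width_scale_lo", 0.8),
            width_scale_hi=cons.get("width_scale_hi", 1.25),
        ),
    )


def load_model_library(directory: str | Path,
                       names: list[str] | None = None
                       ) -> list[PureComponentModel]:
    """Load component models from a directory of YAML files, optionally
    restricted to (and ordered by) ``names``."""
    models = {m.name: m for m in
              (load_model(p) for p in sorted(Path(directory).glob("*.y*ml")))}
    if names is None:
        return list(models.values())
    missing = [n for n in names if n not in models]
    if missing:
        raise KeyError(f"models not found in library: {missing}")
    return [models[n] for n in names]
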