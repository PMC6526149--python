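"""End-to-end workflows built from the module primitives.

These are the compositions the plant actually runs: one-point
calibration on the pure o-FNB stream at start-up, spectrum-by-spectrum
IHM quantification of a campaign, steady-state gating and NMR/NIR
pairing, and the PLSR calibration-transfer study across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ihm, nir_chemometrics as nir, steady_state as sst
from .ihm import CalibrationFactor, PureComponentModel
from .nmr_processing import align_to_reference, auto_phase, baseline_correct
from .plant_simulator import CampaignBundle, synth_nmr_spectrum
from .spectra import Spectrum
from .steady_state import ConcentrationSeries

__all__ = [
    "calibrate_on_pure_stream",
    "process_spectrum",
    "quantify_campaign",
    "pair_campaign",
    "nir_transfer_study",
]


def calibrate_on_pure_stream(spec: Spectrum, model: PureComponentModel,
                             known_conc: float,
                             baseline_order: int = 2) -> CalibrationFactor:
    """One-point calibration on a pure-analyte stream of known
    concentration (start-up o-FNB at 0.63 mol/L on the plant)."""
    fit = ihm.fit_mixture(spec, [model], baseline_order=baseline_order,
                          n_starts=1)
    return ihm.calibrate_xi(fit.area(model.name), model.nu, known_conc,
                            source=f"{model.name}@{known_conc}")


def process_spectrum(spec: Spectrum, ref: Spectrum | None = None,
                     intervals: list[tuple[float, float]] | None = None,
                     baseline_order: int = 2,
                     max_shift: int = 10,
                     n_passes: int = 2) -> Spectrum:
    """Preparation chain on an already-transformed spectrum.

    Baseline and phase estimation are interdependent (phasing re-bends
    whatever baseline was subtracted before it), so the pair is applied
    ``n_passes`` times — two passes settle in practice — followed by
    optional interval alignment to a reference.
    """
    out = spec
    for _ in range(max(n_passes, 1)):
        out = baseline_correct(out, baseline_order)
        if "complex" in out.meta:
            out = auto_phase(out)
    if ref is not None and intervals:
        out = align_to_reference(out, ref, intervals, max_shift)
    return out


def quantify_campaign(bundle: CampaignBundle,
                      models: list[PureComponentModel],
                      xi: CalibrationFactor,
                      process: bool = True,
                      align_ref: Spectrum | None = None,
                      intervals: list[tuple[float, float]] | None = None,
                      per_peak_shifts: bool = False) -> ConcentrationSeries:
    """IHM-quantify every NMR spectrum of a campaign into a
    concentration series.

    Successive spectra warm-start the mixture fit from the previous
    solution, which makes series quantification fast and deterministic.
    Per-peak shifts are off by default here (the global shift + width
    scale capture the drift the simulator generates); turn them on for
    maximum-fidelity single fits.
    """
    nu_map = {m.name: m.nu for m in models}
    rows = []
    x0 = None
    for spec in bundle.nmr_spectra:
        s = process_spectrum(spec, align_ref, intervals) if process else spec
        try:
            fit = ihm.fit_mixture(s, models, per_peak_shifts=per_peak_shifts,
                                  n_starts=1, x0=x0)
            x0 = _pack_from_fit(fit, models, per_peak_shifts)
            conc = ihm.quantify(fit, xi, nu_map)
            conc["residual_norm"] = fit.residual_norm
        except (ValueError, RuntimeError):
            conc = {m.name: np.nan for m in models}
            conc["residual_norm"] = np.nan
            x0 = None
        rows.append(conc)
    df = pd.DataFrame(rows)
    resid = df.pop("residual_norm")
    series = ConcentrationSeries(bundle.nmr_times, df, run_id=bundle.run_id)
    series.residual_norm = resid.to_numpy()  # type: ignore[attr-defined]
    return series


def _pack_from_fit(fit: ihm.MixtureFitResult, models, per_peak_shifts: bool
                   ) -> np.ndarray:
    parts = []
    for i, m in enumerate(models):
        ws = fit.width_scales[i]
        parts += [fit.weights[i] / ws if ws else fit.weights[i],
                  fit.global_shifts[i], ws]
    if per_peak_shifts:
        for m in models:
            parts += list(fit.peak_shifts[m.name])
    parts += list(fit.baseline_coeffs)
    return np.asarray(parts)


def pair_campaign(series: ConcentrationSeries, bundle: CampaignBundle,
                  window: int = sst.DEFAULT_WINDOW,
                  slope_max: float = sst.DEFAULT_SLOPE_MAX,
                  sd_max: float = sst.DEFAULT_SD_MAX,
                  block: int = sst.DEFAULT_BLOCK,
                  delay: float = sst.DEFAULT_DELAY) -> list[sst.PairedSample]:
    """Gate the NMR series for steadiness, smooth, and pair with the
    campaign's NIR spectra at the configured inter-sensor delay."""
    sst.classify_steady(series, window, slope_max, sd_max)
    smoothed = sst.smooth_steady(series, block)
    pairs = sst.pair_references(smoothed, bundle.nir_times, delay=delay)
    for p in pairs:
        p.run_id = bundle.run_id
    return pairs


def nir_transfer_study(bundles: list[CampaignBundle],
                       series_list: list[ConcentrationSeries],
                       analyte: str = "LiNDPA",
                       test_run: str | None = None,
                       config: dict | None = None
                       ) -> nir.ValidationReport:
    """Full calibration-transfer study: pair every run, hold one run
    out, fit PLSR on the rest, report random/systematic CV and test
    RMSE (mmol/L)."""
    cfg = (config or nir.DEFAULT_ANALYTE_CONFIG)[analyte]
    all_pairs: list[sst.PairedSample] = []
    nir_lookup: dict[tuple[str, int], Spectrum] = {}
    for b, s in zip(bundles, series_list):
        pairs = pair_campaign(s, b)
        all_pairs += pairs
        for i, spec in enumerate(b.nir_spectra):
            nir_lookup[(b.run_id, i)] = spec
    if test_run is None:
        test_run = bundles[-1].run_id
    runs = [b.run_id for b in bundles]
    cal_pairs, test_pairs = sst.split_by_run(
        all_pairs, [r for r in runs if r != test_run], test_run)
    if len(cal_pairs) < cfg["n_factors"] + 2 or not test_pairs:
        raise ValueError("not enough paired steady samples for the study")

    axis = bundles[0].nir_spectra[0].axis

    def matrix(pairs):
        X = np.vstack([nir_lookup[(p.run_id, p.nir_spectrum_id)].intensity
                       for p in pairs])
        y = np.array([p.nmr_reference[analyte] for p in pairs])
        return X, y

    X_cal_raw, y_cal = matrix(cal_pairs)
    X_test_raw, y_test = matrix(test_pairs)
    _, X_cal = cfg["preprocess"].apply(axis, X_cal_raw)
    _, X_test = cfg["preprocess"].apply(axis, X_test_raw)

    n_seg = min(20, len(y_cal))
    curve = nir.cross_validate(X_cal, y_cal,
                               {"random_segments": n_seg,
                                "seed": nir.DEFAULT_CV_SEED},
                               [cfg["n_factors"]])
    labels = np.array([p.run_id for p in cal_pairs])
    sys_cv = nir.cross_validate(X_cal, y_cal, {"systematic": labels},
                                [cfg["n_factors"]])
    model = nir.fit_plsr(X_cal, y_cal, cfg["n_factors"], analyte=analyte,
                         preprocess=cfg["preprocess"], axis=axis)
    rmse_test = nir.evaluate_test(model, X_test, y_test)
    return nir.ValidationReport(
        analyte=analyte, n_factors=model.n_factors,
        rmse_cv_random=curve[cfg["n_factors"]],
        rmse_cv_systematic=sys_cv[cfg["n_factors"]],
        rmse_test=rmse_test,
        rmsecv_curve=curve)
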