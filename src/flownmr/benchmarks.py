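"""End-to-end benchmark workflows.

Each function runs one self-contained study on synthetic data and
returns the quantities the study measures; the acceptance script and
the acceptance tests both call these, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import ihm, pipeline, plant_simulator as ps, rto_mawqa as rto
from .steady_state import DEFAULT_SD_MAX, DEFAULT_SLOPE_MAX

__all__ = [
    "one_point_round_trip",
    "ihm_parameter_recovery",
    "steady_classifier_cases",
    "nir_transfer_study_synthetic",
    "mawqa_study",
]


def one_point_round_trip(conc: float = 0.63) -> float:
    """Calibrate xi on a noiseless pure o-FNB spectrum at the start-up
    feed concentration and re-quantify the same spectrum (Eq. 1 both
    ways).  Exact round trip up to float error."""
    models = ps.default_model_library()
    m = next(mm for mm in models if mm.name == "oFNB")
    spec = ps.synth_nmr_spectrum({"oFNB": conc}, models)
    xi = pipeline.calibrate_on_pure_stream(spec, m, conc)
    fit = ihm.fit_mixture(spec, [m], n_starts=1)
    return ihm.quantify(fit, xi, {"oFNB": m.nu})["oFNB"]


def ihm_parameter_recovery(n_spectra: int = 200, seed: int = 42
                           ) -> dict[str, float]:
    """Quantification error study: synthetic mixtures at uniform(0, 1.2)
    mol/L with the simulator's default noise, shift and phase jitter,
    full processing chain, IHM quantification.

    Returns per-analyte RMSE against ground truth in mmol/L plus the
    worst case under ``"max"``.
    """
    models = ps.default_model_library()
    nu_map = {m.name: m.nu for m in models}
    xi = ihm.CalibrationFactor(ps.XI_TRUE)
    params = ps.PlantParams()
    rng = np.random.default_rng(seed)
    sq = {m.name: 0.0 for m in models}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_spectra):
            conc = {m.name: float(rng.uniform(0.0, 1.2)) for m in models}
            spec = ps.synth_nmr_spectrum(
                conc, models, noise_sd=params.nmr_noise_sd,
                shift_error=rng.normal(0.0, params.shift_error_sd),
                phase_error_deg=rng.normal(0.0, params.phase_error_sd),
                rng=rng)
            prepared = pipeline.process_spectrum(spec)
            fit = ihm.fit_mixture(prepared, models, per_peak_shifts=True,
                                  n_starts=1)
            est = ihm.quantify(fit, xi, nu_map)
            for name in sq:
                sq[name] += (est[name] - conc[name]) ** 2
    rmse = {name: float(np.sqrt(v / n_spectra)) * 1000.0
            for name, v in sq.items()}
    rmse["max"] = max(rmse.values())
    return rmse


def steady_classifier_cases() -> tuple[bool, bool, bool]:
    """The three constructed series of the moving-window rule: constant
    (steady), a 0.24 mol/L/h ramp (transient by slope), a +-0.02 mol/L
    oscillation (transient by SD).  Returns their centre-point flags."""
    import pandas as pd

    from .steady_state import ConcentrationSeries, classify_steady

    ts = np.arange(21) * 15.0 + 15.0

    def flag(vals):
        s = ConcentrationSeries(ts, pd.DataFrame({"c": vals}))
        return bool(classify_steady(s, slope_max=DEFAULT_SLOPE_MAX,
                                    sd_max=DEFAULT_SD_MAX)[10])

    constant = flag(np.full(21, 0.5))
    ramp = flag(0.5 + 0.001 * np.arange(21))          # 0.24 mol/L/h
    oscillation = flag(0.52 + 0.02 * (-1.0) ** np.arange(21))
    return constant, ramp, oscillation


def nir_transfer_study_synthetic(seed: int = 1, n_runs: int = 4,
                                 analyte: str = "LiNDPA",
                                 n_holds: int = 5,
                                 hold_s: float = 600.0) -> dict[str, float]:
    """Calibration-transfer study on a synthetic multi-run campaign.

    Each run is simulated with its own seed, NMR-quantified, steady-
    gated, paired with the run's NIR spectra; the last run is held out.
    Returns the held-out RMSE and CV summaries in mmol/L.
    """
    models = ps.default_model_library()
    xi = ihm.CalibrationFactor(ps.XI_TRUE)
    bundles, series = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_runs):
            run_seed = seed * 1000 + k
            rng = np.random.default_rng(run_seed)
            sched = ps.default_schedule(rng, n_holds=n_holds, hold_s=hold_s)
            bundle = ps.run_campaign(sched, seed=run_seed,
                                     run_id=f"day{k + 1}")
            bundles.append(bundle)
            series.append(pipeline.quantify_campaign(bundle, models, xi))
        report = pipeline.nir_transfer_study(
            bundles, series, analyte=analyte, test_run=f"day{n_runs}")
    return {
        "rmse_test": report.rmse_test,
        "rmse_cv_random": report.rmse_cv_random,
        "rmse_cv_systematic": report.rmse_cv_systematic,
        "n_factors": report.n_factors,
    }


def mawqa_study(seed: int = 7, noise_sd: float = 0.0,
                max_iter: int = 30, grid_n: int = 51) -> dict[str, float]:
    """MAWQA against the default mismatched virtual plant from the
    start-up flows, with the brute-force grid oracle for reference.

    ``noise_sd`` (mol/m^3) adds measurement noise to the product
    concentration; 0 is the noiseless oracle mode.  Returns the final
    operating point's profit, the grid optimum, their gap, and the
    converged LiHMDS:aniline molar feed ratio.
    """
    plant = rto.simulated_plant(noise_sd=noise_sd, seed=seed)
    model = rto.nominal_model()
    traj = rto.run_mawqa(plant, model, np.array([3.58, 3.58, 3.58]),
                         config=rto.MAWQAConfig(max_iter=max_iter))
    final = [p for p in traj if p.phase == "iterate"][-1]
    exact_plant = rto.simulated_plant()
    u_star, p_star = rto.grid_optimum(exact_plant, n=grid_n)
    profit_final = rto.profit(final.u, exact_plant(final.u))
    return {
        "final_u": final.u.tolist(),
        "profit_final": float(profit_final),
        "profit_grid_optimum": float(p_star),
        "gap_percent": float(100.0 * (p_star - profit_final) / abs(p_star)),
        "molar_ratio": float(rto.feed_molar_ratio(final.u)),
        "n_plant_evaluations": len(traj),
        "profit_start": float([p for p in traj if p.phase == "iterate"][0]
                              .profit_plant),
    }
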