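"""Virtual lithiation plant and forward spectrum synthesis.

The simulated process is the continuous coupling of aniline and
1-fluoro-2-nitrobenzene (o-FNB) with lithium hexamethyldisilazane
(LiHMDS, fed in >= 2:1 molar excess) in THF, yielding lithium
2-nitrodiphenylamine (Li-NDPA) with the lithiated aniline as an
observable intermediate.  The reactor model is deliberately simple —
stoichiometry, a smooth saturating conversion law in the LiHMDS excess,
and a moisture sink consuming base — because the monitoring and
optimization layers above it are the object of study, not the kinetics.

The module also synthesizes the sensor data: 43-MHz proton spectra as
pseudo-Voigt superpositions whose area per proton is proportional to
concentration (with noise, ppm drift and phase error), and FT-NIR
absorbance spectra with analyte-linear Gaussian bands, multiplicative
scatter and noise-dominated edge regions.  :func:`run_campaign` ties it
together into a timestamped, seeded campaign bundle with ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .ihm import ModelConstraints, PseudoVoigtPeak, PureComponentModel
from .spectra import FID, Spectrum

__all__ = [
    "FeedStream",
    "PlantParams",
    "OutletState",
    "reactor_steady_state",
    "true_plant",
    "default_feeds",
    "default_model_library",
    "default_band_library",
    "synth_nmr_spectrum",
    "synth_nir_spectrum",
    "spectrum_to_fid",
    "run_campaign",
    "CampaignBundle",
    "NMR_PPM_GRID",
    "NIR_GRID",
    "XI_TRUE",
]

ANALYTES = ["aniline", "oFNB", "LiHMDS", "Lianiline", "LiNDPA"]

#: proton counts used by the forward model and the nu map
NU = {"aniline": 5, "oFNB": 4, "LiHMDS": 18, "Lianiline": 5, "LiNDPA": 9}

#: ground-truth conversion factor of the synthetic spectrometer,
#: (mol/L) per (area/nucleus); fixed so forward synthesis and one-point
#: calibration are mutually consistent
XI_TRUE = 1.0

#: default NMR axis: 0-11 ppm at 43.32 MHz
NMR_PPM_GRID = np.linspace(0.0, 11.0, 2048)

#: FT-NIR grid: 2074 points over 4000-12000 cm^-1
NIR_GRID = np.linspace(4000.0, 12000.0, 2074)

#: regions of the NIR spectrum dominated by absorption/detector noise
NIR_NOISY_LO = (4000.0, 4611.0)
NIR_NOISY_HI = (8975.0, 12000.0)


@dataclass
class FeedStream:
    """One THF feed solution: mass flow, analyte concentration, density."""

    species: str
    mass_flow: float        # kg/h
    conc: float             # mol/L in THF
    density: float = 0.90   # kg/L

    def __post_init__(self) -> None:
        if self.mass_flow < 0 or self.conc < 0 or self.density <= 0:
            raise ValueError("invalid feed stream parameters")

    @property
    def molar_flow(self) -> float:
        """mol/h delivered by this stream."""
        return self.mass_flow / self.density * self.conc


def default_feeds(u: tuple[float, float, float] | None = None,
                  concs: dict[str, float] | None = None) -> dict[str, FeedStream]:
    """Start-up feed set: o-FNB 5.60, aniline 3.68, LiHMDS 6.89 kg/h at
    0.63 / 0.96 / 1.10 mol/L (LiHMDS excess factor 2.14)."""
    c = {"aniline": 0.96, "LiHMDS": 1.10, "oFNB": 0.63}
    if concs:
        c.update(concs)
    flows = {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60}
    if u is not None:
        flows = {"aniline": u[0], "LiHMDS": u[1], "oFNB": u[2]}
    return {s: FeedStream(s, flows[s], c[s]) for s in flows}


@dataclass
class PlantParams:
    """Reactor + sensor parameters of the virtual plant.

    ``k_sat`` shapes the saturating conversion law
    eta = excess / (excess + k_sat); ``moisture_sink`` is the molar flow
    of LiHMDS lost to residual water; ``intermediate_fraction`` is the
    share of unreacted aniline present in its lithiated form.
    ``mixing_efficiency`` (< 1 only for the "true" plant) emulates
    imperfect mixing in the tubular reactor.
    """

    k_sat: float = 0.05
    moisture_sink: float = 0.3          # mol/h LiHMDS
    intermediate_fraction: float = 0.30
    mixing_efficiency: float = 1.0
    #: mol/h scale over which the limiting-reactant switch is blended;
    #: a tubular reactor transitions smoothly between limiting regimes,
    #: and the blending keeps the profit surface differentiable for RTO
    smoothing: float = 0.25
    rho_mixture: float = 900.0          # kg/m^3
    nmr_noise_sd: float = 0.012         # intensity units of the synthetic spectra
    nir_noise_sd: float = 0.0015        # AU, working region
    nir_edge_noise_factor: float = 20.0
    shift_error_sd: float = 0.002       # ppm, shot-to-shot field jitter
    phase_error_sd: float = 0.5         # degrees, zero-order jitter
    delay_nmr: float = 30.0             # s, reactor -> NMR cell
    delay_nir: float = 150.0            # s, reactor -> NIR cell (120 s after NMR)
    sampling_nmr: float = 15.0          # s
    sampling_nir: float = 160.0         # s
    relax_tau: float = 120.0            # s, first-order set-point relaxation

    def __post_init__(self) -> None:
        if self.rho_mixture <= 0:
            raise ValueError("rho_mixture must be positive")
        for name in ("k_sat", "moisture_sink", "nmr_noise_sd", "nir_noise_sd",
                     "delay_nmr", "delay_nir", "sampling_nmr", "sampling_nir"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: the plant the optimizer does NOT know: different conversion shape,
#: larger moisture loss, imperfect mixing
TRUE_PLANT_PARAMS = PlantParams(k_sat=0.12, moisture_sink=0.6,
                                intermediate_fraction=0.30,
                                mixing_efficiency=0.95)


def _smooth_min(a: float, b: float, eps: float) -> float:
    """C^1 blend of min(a, b); exact min when eps = 0, undershooting by
    at most eps/2 at a tie and by eps^2/(8|a-b|) far from it."""
    if eps <= 0:
        return min(a, b)
    return 0.5 * (a + b - np.sqrt((a - b) ** 2 + eps ** 2))


@dataclass
class OutletState:
    """Steady-state reactor outlet."""

    concentrations: dict[str, float]    # mol/m^3
    total_mass_flow: float              # kg/h
    molar_flows: dict[str, float]       # mol/h, for balance checks

    def conc_mol_per_L(self) -> dict[str, float]:
        return {k: v / 1000.0 for k, v in self.concentrations.items()}


def reactor_steady_state(feeds: dict[str, FeedStream],
                         params: PlantParams | None = None) -> OutletState:
    """Stoichiometric steady-state model with saturating conversion.

    1 aniline + 1 o-FNB + 2 LiHMDS -> 1 Li-NDPA (+ LiF + amine).  The
    extent is the limiting molar flow times
    eta = excess / (excess + k_sat), where excess is the effective
    LiHMDS flow (after the moisture sink) over twice the limiting
    reactant.  A fixed fraction of the unreacted aniline leaves as the
    lithiated intermediate, consuming one LiHMDS each.
    """
    params = params or PlantParams()
    for sp in ("aniline", "LiHMDS", "oFNB"):
        if sp not in feeds:
            raise ValueError(f"missing feed stream '{sp}'")
    total_u = sum(f.mass_flow for f in feeds.values())
    if total_u <= 0:
        raise ValueError("zero total feed flow")
    n_an = feeds["aniline"].molar_flow
    n_fnb = feeds["oFNB"].molar_flow
    n_li = max(feeds["LiHMDS"].molar_flow - params.moisture_sink, 0.0)

    limiting = _smooth_min(n_an, n_fnb, params.smoothing)
    if limiting <= 0 or n_li <= 0:
        extent = 0.0
    else:
        excess = n_li / (2.0 * limiting)
        eta = excess / (excess + params.k_sat) * params.mixing_efficiency
        extent = _smooth_min(limiting, n_li / 2.0, params.smoothing) * eta
    extent = max(extent, 0.0)

    li_after = n_li - 2.0 * extent
    lian = min(params.intermediate_fraction * (n_an - extent), max(li_after, 0.0))
    flows = {
        "aniline": n_an - extent - lian,
        "oFNB": n_fnb - extent,
        "LiHMDS": li_after - lian,
        "Lianiline": lian,
        "LiNDPA": extent,
    }
    vol_flow = total_u / params.rho_mixture        # m^3/h
    conc = {k: v / vol_flow for k, v in flows.items()}
    return OutletState(concentrations=conc, total_mass_flow=total_u,
                       molar_flows=flows)


def true_plant(feeds: dict[str, FeedStream],
               params_true: PlantParams | None = None) -> OutletState:
    """Ground-truth plant: same structure, mismatched parameters plus a
    mixing-efficiency factor, so the nominal model is wrong."""
    return reactor_steady_state(feeds, params_true or TRUE_PLANT_PARAMS)


# ---------------------------------------------------------------------------
# spectral forward models


def _pv_peaks(*rows: tuple[float, float, float, float]) -> list[PseudoVoigtPeak]:
    return [PseudoVoigtPeak(position=p, height=h, fwhm=w, gauss_fraction=g)
            for p, h, w, g in rows]


def default_model_library() -> list[PureComponentModel]:
    """Pseudo-Voigt pure-component models of the five analytes at
    43 MHz.

    Positions and ~0.05-ppm linewidths are representative of a benchtop
    instrument: aromatic multiplets collapse to a few broad lines, the
    LiHMDS trimethylsilyl protons sit near 0.1 ppm.  Peak heights are
    chosen so each model's total area equals its proton count nu — a
    1 mol/L stream at unit weight then satisfies c = XI_TRUE * A / nu
    exactly.
    """
    cons = ModelConstraints()

    def scaled(name: str, nu: int, rows: list[tuple[float, float, float, float]]
               ) -> PureComponentModel:
        peaks = _pv_peaks(*rows)
        total = sum(p.area for p in peaks)
        for p in peaks:
            p.height *= nu / total
        return PureComponentModel(name=name, peaks=peaks, nu=nu, constraints=cons)

    # rows: (position ppm, raw height, fwhm ppm, gauss fraction)
    return [
        scaled("aniline", NU["aniline"], [
            (6.62, 3.0, 0.055, 0.4), (7.08, 2.0, 0.055, 0.4)]),
        scaled("oFNB", NU["oFNB"], [
            (7.28, 2.0, 0.050, 0.5), (7.62, 1.0, 0.050, 0.5),
            (8.02, 1.0, 0.045, 0.5)]),
        scaled("LiHMDS", NU["LiHMDS"], [(0.12, 18.0, 0.040, 0.5)]),
        scaled("Lianiline", NU["Lianiline"], [
            (6.32, 2.0, 0.060, 0.4), (6.88, 3.0, 0.060, 0.4)]),
        scaled("LiNDPA", NU["LiNDPA"], [
            (6.75, 2.0, 0.060, 0.4), (7.15, 3.0, 0.055, 0.4),
            (7.48, 3.0, 0.055, 0.4), (8.12, 1.0, 0.050, 0.5)]),
    ]


def synth_nmr_spectrum(conc: dict[str, float],
                       models: list[PureComponentModel],
                       noise_sd: float = 0.0,
                       shift_error: float = 0.0,
                       phase_error_deg: float = 0.0,
                       ppm: np.ndarray | None = None,
                       rng: np.random.Generator | None = None,
                       xi: float = XI_TRUE) -> Spectrum:
    """Forward-synthesize a 43-MHz proton spectrum from concentrations.

    Each component is scaled so its absolute area A satisfies
    c = xi * A / nu.  ``shift_error`` displaces every peak globally
    (ppm); ``phase_error_deg`` rotates the complex spectrum (imaginary
    channel from the Hilbert transform); white noise is added on top.
    The complex spectrum is stored in ``meta["complex"]``.
    """
    ppm = NMR_PPM_GRID if ppm is None else np.asarray(ppm, float)
    rng = rng or np.random.default_rng()
    clean = np.zeros_like(ppm)
    for m in models:
        c = float(conc.get(m.name, 0.0))
        if c <= 0:
            continue
        weight = c * m.nu / (xi * m.reference_area)
        clean += m.evaluate(ppm, weight=weight, global_shift=shift_error)
    # analytic signal: real part is the absorption, imaginary the
    # Hilbert dispersion; a zero-order phase error rotates the pair
    cplx = hilbert(clean) * np.exp(-1j * np.deg2rad(phase_error_deg))
    real = cplx.real.copy()
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, ppm.size)
        real = real + noise
        cplx = cplx + noise  # noise enters the detected (real) channel
    return Spectrum(ppm, real, {
        "domain": "nmr", "spectrometer_freq": 43.32, "complex": cplx,
        "truth": dict(conc), "xi_true": xi,
    })


def spectrum_to_fid(spec: Spectrum, dwell_time: float | None = None) -> FID:
    """Inverse-FT a (complex) spectrum into a FID for processing tests."""
    cplx = np.asarray(spec.meta.get("complex", spec.intensity), complex)
    samples = np.fft.ifft(np.fft.ifftshift(cplx))
    f0 = float(spec.meta.get("spectrometer_freq", 43.32))
    if dwell_time is None:
        sw_hz = abs(spec.axis[-1] - spec.axis[0]) * f0
        dwell_time = 1.0 / sw_hz
    return FID(samples=samples, dwell_time=dwell_time, spectrometer_freq=f0)


#: Gaussian NIR band library: per analyte, (centre cm^-1, width cm^-1,
#: absorbance per mol/L).  All quantitative bands sit inside the
#: working window 4611-8957 cm^-1; overlaps are intentional.
def default_band_library() -> dict[str, list[tuple[float, float, float]]]:
    return {
        "aniline": [(6050.0, 120.0, 0.30), (8750.0, 200.0, 0.10)],
        "oFNB": [(6150.0, 90.0, 0.25), (5100.0, 150.0, 0.15)],
        "LiHMDS": [(5700.0, 180.0, 0.15)],
        "Lianiline": [(7000.0, 130.0, 0.22), (5300.0, 160.0, 0.12)],
        "LiNDPA": [(5900.0, 140.0, 0.28), (6900.0, 220.0, 0.18),
                   (4900.0, 100.0, 0.10)],
    }


#: fixed THF/solvent background bands (absorbance, concentration-free)
_SOLVENT_BANDS = [(4350.0, 250.0, 0.60), (5800.0, 600.0, 0.20),
                  (8400.0, 500.0, 0.08)]


def synth_nir_spectrum(conc: dict[str, float],
                       band_library: dict[str, list[tuple[float, float, float]]]
                       | None = None,
                       noise_sd: float = 0.0015,
                       scatter: bool = True,
                       edge_noise_factor: float = 20.0,
                       grid: np.ndarray | None = None,
                       rng: np.random.Generator | None = None) -> Spectrum:
    """Forward-synthesize an FT-NIR absorbance spectrum.

    Absorbance is linear in the analyte concentrations (mol/L) through
    Gaussian bands, on top of a fixed solvent background.  Scatter is a
    random multiplicative gain and additive offset (both removable by
    SNV); noise is heteroscedastic, amplified in the 12000-8975 and
    4611-4000 cm^-1 edge regions.
    """
    grid = NIR_GRID if grid is None else np.asarray(grid, float)
    bands = band_library or default_band_library()
    rng = rng or np.random.default_rng()
    absorb = np.zeros_like(grid)
    for centre, width, strength in _SOLVENT_BANDS:
        absorb += strength * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    for name, blist in bands.items():
        c = float(conc.get(name, 0.0))
        if c <= 0:
            continue
        for centre, width, strength in blist:
            absorb += c * strength * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    if scatter:
        gain = rng.normal(1.0, 0.05)
        offset = rng.normal(0.0, 0.01)
        absorb = gain * absorb + offset
    if noise_sd > 0:
        sd = np.full_like(grid, noise_sd)
        edge = ((grid >= NIR_NOISY_HI[0]) | (grid <= NIR_NOISY_LO[1]))
        sd[edge] *= edge_noise_factor
        absorb = absorb + rng.normal(0.0, 1.0, grid.size) * sd
    return Spectrum(grid, absorb, {"domain": "nir", "truth": dict(conc)})


# ---------------------------------------------------------------------------
# campaign simulation


@dataclass
class CampaignBundle:
    """Everything one simulated production run emits.

    ``ground_truth`` holds the true outlet concentrations (mol/L) at the
    NMR sensor times; ``nir_truth`` the same at the NIR sensor times.
    Deterministic given the manifest's seed.
    """

    run_id: str
    nmr_times: np.ndarray
    nmr_spectra: list[Spectrum]
    nir_times: np.ndarray
    nir_spectra: list[Spectrum]
    ground_truth: pd.DataFrame
    nir_truth: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def save(self, directory: str | Path, spectra_format: str = "csv") -> None:
        from . import io as fio
        d = Path(directory)
        (d / "nmr").mkdir(parents=True, exist_ok=True)
        (d / "nir").mkdir(parents=True, exist_ok=True)
        ext = ".jdx" if spectra_format == "jcamp" else ".csv"
        for t, s in zip(self.nmr_times, self.nmr_spectra):
            fio.write_spectrum(s, d / "nmr" / f"nmr_{int(t):06d}{ext}")
        for t, s in zip(self.nir_times, self.nir_spectra):
            fio.write_spectrum(s, d / "nir" / f"nir_{int(t):06d}{ext}")
        self.ground_truth.to_csv(d / "ground_truth.csv", index=False)
        self.nir_truth.to_csv(d / "nir_truth.csv", index=False)
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _interp_state(t: float, holds: list[tuple[float, dict[str, float]]],
                  tau: float, plant_fun, params: PlantParams,
                  feed_concs: list[tuple[float, dict[str, float]]]) -> dict[str, float]:
    """Outlet concentration (mol/L) at time t: first-order relaxation of
    the steady-state map across set-point (and feed-batch) changes."""
    # break the timeline at every set-point or feed-concentration change
    events = sorted({t0 for t0, _ in holds} | {tc for tc, _ in feed_concs})
    events = [e for e in events if e <= t] or [holds[0][0]]

    def target_at(time: float) -> dict[str, float]:
        u = holds[0][1]
        for t0, uu in holds:
            if time >= t0:
                u = uu
        concs: dict[str, float] = {}
        for tc, cdict in feed_concs:
            if time >= tc:
                concs = {**concs, **cdict}
        return plant_fun(default_feeds(
            (u["aniline"], u["LiHMDS"], u["oFNB"]), concs), params
        ).conc_mol_per_L()

    # sweep forward: state relaxes first-order toward the segment target
    state = target_at(events[0])
    for i, t0 in enumerate(events):
        t1 = events[i + 1] if i + 1 < len(events) else t
        target = target_at(t0)
        lam = np.exp(-max(t1 - t0, 0.0) / tau) if tau > 0 else 0.0
        state = {k: target[k] + (state[k] - target[k]) * lam for k in target}
    return state


def run_campaign(schedule: list[tuple[float, dict[str, float]]],
                 params: PlantParams | None = None,
                 seed: int = 0,
                 duration: float | None = None,
                 run_id: str = "run",
                 models: list[PureComponentModel] | None = None,
                 plant: str = "true",
                 feed_conc_changes: list[tuple[float, dict[str, float]]]
                 | None = None) -> CampaignBundle:
    """Simulate one production run.

    ``schedule`` is a list of ``(t_start_s, {"aniline": u1, "LiHMDS":
    u2, "oFNB": u3})`` mass-flow set-points held until the next entry;
    outlet concentrations relax first-order (time constant
    ``params.relax_tau``) between the corresponding steady states.  NMR
    spectra are emitted every 15 s and NIR spectra every 160 s, each
    reflecting the outlet ``delay_nmr`` / ``delay_nir`` seconds earlier
    (a 120-s inter-sensor offset).  ``feed_conc_changes`` injects feed
    batch disturbances, e.g. ``[(3000.0, {"LiHMDS": 1.00})]``.
    """
    params = params or TRUE_PLANT_PARAMS
    models = models or default_model_library()
    rng = np.random.default_rng(seed)
    if not schedule or any(schedule[i][0] >= schedule[i + 1][0]
                           for i in range(len(schedule) - 1)):
        raise ValueError("schedule must be non-empty with increasing times")
    plant_fun = reactor_steady_state
    t_end = duration if duration is not None else schedule[-1][0] + 600.0
    feed_concs = feed_conc_changes or []

    def outlet_at(t: float) -> dict[str, float]:
        return _interp_state(max(t, 0.0), schedule, params.relax_tau,
                             plant_fun, params, feed_concs)

    nmr_times = np.arange(schedule[0][0] + params.sampling_nmr, t_end,
                          params.sampling_nmr)
    nir_times = np.arange(schedule[0][0] + params.sampling_nir, t_end,
                          params.sampling_nir)

    gt_rows, nmr_spectra = [], []
    for t in nmr_times:
        c = outlet_at(t - params.delay_nmr)
        gt_rows.append({"timestamp": t, **c})
        nmr_spectra.append(synth_nmr_spectrum(
            c, models,
            noise_sd=params.nmr_noise_sd,
            shift_error=rng.normal(0.0, params.shift_error_sd),
            phase_error_deg=rng.normal(0.0, params.phase_error_sd),
            rng=rng))
    nir_rows, nir_spectra = [], []
    for t in nir_times:
        c = outlet_at(t - params.delay_nir)
        nir_rows.append({"timestamp": t, **c})
        nir_spectra.append(synth_nir_spectrum(
            c, noise_sd=params.nir_noise_sd,
            edge_noise_factor=params.nir_edge_noise_factor, rng=rng))

    manifest = {
        "run_id": run_id, "seed": int(seed), "plant": plant,
        "schedule": [[t, u] for t, u in schedule],
        "feed_conc_changes": [[t, c] for t, c in feed_concs],
        "params": {k: v for k, v in asdict(params).items()},
    }
    return CampaignBundle(
        run_id=run_id,
        nmr_times=nmr_times, nmr_spectra=nmr_spectra,
        nir_times=nir_times, nir_spectra=nir_spectra,
        ground_truth=pd.DataFrame(gt_rows),
        nir_truth=pd.DataFrame(nir_rows),
        manifest=manifest)


def default_schedule(rng: np.random.Generator, n_holds: int = 5,
                     hold_s: float = 600.0,
                     spread: float = 0.30) -> list[tuple[float, dict[str, float]]]:
    """Random set-point schedule around the start-up flows (±spread),
    one hold per ~10 min as in iterative plant optimization."""
    base = {"aniline": 3.68, "LiHMDS": 6.89, "oFNB": 5.60}
    sched = []
    for k in range(n_holds):
        u = {s: float(v * (1.0 + rng.uniform(-spread, spread)))
             for s, v in base.items()}
        sched.append((k * hold_s, u))
    return sched
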