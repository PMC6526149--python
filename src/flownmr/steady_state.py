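"""Steady-state gating of online concentration series.

Only measurements taken during steady plant operation may serve as
calibration references for the NIR spectrometer: transient phases would
let concentration gradients travel between the two sensors while a
spectrum is being acquired.  A state is called steady when a moving
11-point linear fit has both |slope| below 0.1 mol L^-1 h^-1 and a
residual standard deviation below 0.01 mol L^-1 — jointly for every
monitored analyte.  Steady stretches are then smoothed with a trailing
6-point moving average, and NMR references are matched to NIR spectra
after compensating the 2-min inter-sensor delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationSeries",
    "PairedSample",
    "classify_steady",
    "smooth_steady",
    "pair_references",
    "split_by_run",
]

#: thresholds printed for the moving-window classifier
DEFAULT_WINDOW = 11
DEFAULT_SLOPE_MAX = 0.1    # mol L^-1 h^-1
DEFAULT_SD_MAX = 0.01      # mol L^-1
DEFAULT_BLOCK = 6
DEFAULT_DELAY = 120.0      # s, NIR lags NMR


@dataclass
class ConcentrationSeries:
    """Timestamped per-analyte molar concentrations with steady flags.

    ``values`` is a DataFrame with one column per analyte (mol/L; NaN
    marks a failed quantification), indexed positionally alongside
    ``timestamps`` (seconds, strictly increasing; nominal 15-s spacing
    for the NMR sensor).
    """

    timestamps: np.ndarray
    values: pd.DataFrame
    flags: np.ndarray | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "timestamp", self.timestamps)
        if self.flags is not None:
            df["steady"] = self.flags
        if self.run_id is not None:
            df["run"] = self.run_id
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationSeries":
        df = df.copy()
        ts = df.pop("timestamp").to_numpy(float)
        flags = df.pop("steady").to_numpy(bool) if "steady" in df else None
        run = None
        if "run" in df:
            runs = df.pop("run").unique()
            run = str(runs[0]) if len(runs) == 1 else None
        return cls(ts, df, flags, run)


@dataclass
class PairedSample:
    """One NIR spectrum matched to a smoothed steady NMR reference."""

    nir_spectrum_id: int | str
    nir_time: float
    nmr_time: float
    nmr_reference: dict[str, float] = field(default_factory=dict)
    time_offset_applied: float = DEFAULT_DELAY
    run_id: str | None = None


def classify_steady(series: ConcentrationSeries,
                    window: int = DEFAULT_WINDOW,
                    slope_max: float = DEFAULT_SLOPE_MAX,
                    sd_max: float = DEFAULT_SD_MAX) -> np.ndarray:
    """Flag each point steady/transient by a centred moving linear fit.

    For every analyte a centred ``window``-point OLS line is fitted;
    the point is steady iff, for *every* analyte, |slope| < ``slope_max``
    (mol/L/h) and the SD of the fit residuals < ``sd_max`` (mol/L).
    Edge points without a full window are transient.  NaN values mark
    the affected windows transient.
    """
    n = len(series)
    if n < window:
        raise ValueError(f"need at least {window} points")
    dt = np.diff(series.timestamps)
    nominal = float(np.median(dt))
    if np.any(np.abs(dt - nominal) > 0.10 * nominal):
        warnings.warn("non-uniform sampling beyond 10% jitter; "
                      "proceeding on nominal spacing")
    half = window // 2
    t_h = (np.arange(window) - half) * nominal / 3600.0  # hours, centred
    sxx = float(np.sum(t_h ** 2))
    flags = np.zeros(n, dtype=bool)
    vals = series.values.to_numpy(float)
    for i in range(half, n - half):
        win = vals[i - half: i + half + 1]
        if np.any(~np.isfinite(win)):
            continue
        ok = True
        for a in range(win.shape[1]):
            y = win[:, a]
            slope = float(np.dot(t_h, y - y.mean()) / sxx)
            resid = y - y.mean() - slope * t_h
            # ddof=2: two parameters estimated by the line
            sd = float(np.sqrt(np.sum(resid ** 2) / max(window - 2, 1)))
            if abs(slope) >= slope_max or sd >= sd_max:
                ok = False
                break
        flags[i] = ok
    series.flags = flags
    return flags


def smooth_steady(series: ConcentrationSeries,
                  block: int = DEFAULT_BLOCK) -> ConcentrationSeries:
    """Smooth steady points with a trailing ``block``-point moving
    average taken over steady points only; transient points pass
    through untouched."""
    if series.flags is None:
        raise ValueError("classify_steady must run first")
    vals = series.values.to_numpy(float).copy()
    out = vals.copy()
    steady_idx = np.flatnonzero(series.flags)
    for pos, i in enumerate(steady_idx):
        take = steady_idx[max(pos - block + 1, 0): pos + 1]
        out[i] = vals[take].mean(axis=0)
    smoothed = pd.DataFrame(out, columns=series.values.columns)
    return ConcentrationSeries(series.timestamps.copy(), smoothed,
                               series.flags.copy(), series.run_id)


def pair_references(nmr: ConcentrationSeries, nir_times: np.ndarray,
                    delay: float = DEFAULT_DELAY,
                    max_gap: float = 15.0,
                    nir_ids: list | None = None) -> list[PairedSample]:
    """Match each NIR spectrum to the nearest steady NMR reference.

    For a NIR timestamp ``t`` the nearest NMR point to ``t - delay`` is
    located (ties -> earlier point).  The spectrum is paired only if
    that point is steady and within ``max_gap`` seconds; otherwise it is
    left for the transient test pool.
    """
    if nmr.flags is None:
        raise ValueError("classify_steady must run first")
    nir_times = np.asarray(nir_times, dtype=float)
    if nir_ids is None:
        nir_ids = list(range(len(nir_times)))
    if not nmr.flags.any():
        warnings.warn("no steady NMR points: empty pairing")
        return []
    pairs: list[PairedSample] = []
    ts = nmr.timestamps
    for sid, t in zip(nir_ids, nir_times):
        target = t - delay
        gaps = np.abs(ts - target)
        best = float(gaps.min())
        # tie-break: earlier timestamp
        j = int(np.flatnonzero(gaps <= best + 1e-9)[0])
        if not nmr.flags[j] or gaps[j] > max_gap:
            continue
        ref = {c: float(nmr.values[c].iloc[j]) for c in nmr.values.columns}
        pairs.append(PairedSample(
            nir_spectrum_id=sid, nir_time=float(t), nmr_time=float(ts[j]),
            nmr_reference=ref, time_offset_applied=delay, run_id=nmr.run_id))
    return pairs


def split_by_run(pairs: list[PairedSample], calibration_runs: list[str],
                 test_run: str) -> tuple[list[PairedSample], list[PairedSample]]:
    """Partition paired samples by run id into calibration and test sets."""
    known = set(calibration_runs) | {test_run}
    seen = {p.run_id for p in pairs}
    unknown = seen - known
    if unknown:
        raise ValueError(f"pairs carry unknown run ids: {sorted(map(str, unknown))}")
    cal = [p for p in pairs if p.run_id in set(calibration_runs)]
    test = [p for p in pairs if p.run_id == test_run]
    if not test:
        warnings.warn(f"test run '{test_run}' contains no pairs")
    return cal, test
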