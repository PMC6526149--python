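"""Core spectral containers shared by all modules.

A :class:`Spectrum` is the common currency of the package: a strictly
monotone axis (ppm for NMR, cm^-1 for NIR) with real intensities and a
free-form metadata dict.  A :class:`FID` holds the complex time-domain
NMR signal before Fourier transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["FID", "Spectrum"]


@dataclass
class FID:
    """Free induction decay: complex time-domain NMR samples.

    Parameters
    ----------
    samples
        Complex time-domain values.
    dwell_time
        Sampling interval in seconds (> 0).
    spectrometer_freq
        Proton frequency in MHz (43.32 for the benchtop instrument
        this package models).
    """

    samples: np.ndarray
    dwell_time: float
    spectrometer_freq: float = 43.32

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.n_points < 2:
            raise ValueError("FID needs at least 2 samples")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")

    @property
    def n_points(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_points) * self.dwell_time


@dataclass
class Spectrum:
    """A 1-D spectrum: axis + real intensities + metadata.

    The axis is stored strictly ascending (ppm or cm^-1); display
    conventions (NMR plots run right-to-left) are the caller's concern.
    ``meta`` carries acquisition descriptors; NMR processing stores the
    complex post-FT intensities under ``meta["complex"]`` so that phase
    correction can run after the transform.
    """

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensity must be 1-D and equal length")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if np.all(np.diff(self.axis) < 0):  # store ascending
            self.axis = self.axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
            if "complex" in self.meta:
                self.meta["complex"] = np.asarray(self.meta["complex"])[::-1].copy()

    def __len__(self) -> int:
        return self.axis.size

    @property
    def step(self) -> float:
        """Mean axis increment."""
        return float((self.axis[-1] - self.axis[0]) / max(len(self) - 1, 1))

    def copy(self, intensity: np.ndarray | None = None, **meta: Any) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(
            self.axis.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            new_meta,
        )

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to the closed axis window [lo, hi]."""
        lo, hi = min(lo, hi), max(lo, hi)
        mask = (self.axis >= lo) & (self.axis <= hi)
        if not mask.any():
            raise ValueError(f"window [{lo}, {hi}] outside axis range")
        return Spectrum(self.axis[mask], self.intensity[mask], dict(self.meta))

    def integral(self) -> float:
        """Trapezoidal integral over the full axis."""
        return float(np.trapezoid(self.intensity, self.axis))
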