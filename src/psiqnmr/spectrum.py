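"""Core containers for 1D proton spectra.

A :class:`Spectrum` is a sampled 1D NMR spectrum: a strictly increasing
chemical-shift axis in ppm, an intensity array in arbitrary units, and the
acquisition metadata needed downstream (spectrometer frequency, number of
co-added scans, inter-scan relaxation delay).  Display convention (ppm
decreasing left to right) is a presentation concern; storage is always
increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["AcquisitionParams", "Spectrum"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings for a simulated or recorded 1D spectrum.

    Parameters
    ----------
    spectrometer_mhz : float
        Proton Larmor frequency in MHz; converts Hz couplings/linewidths
        to ppm.
    n_points : int
        Number of samples across the spectral window.
    window_ppm : tuple of float
        (low, high) ppm bounds of the axis.
    linewidth_hz : float
        Full width at half maximum of a single line, in Hz.
    n_scans : int
        Number of co-added scans; signal grows linearly, noise as sqrt.
    relaxation_delay_s : float
        Inter-scan delay in seconds; controls partial T1 recovery.
    noise_sigma : float
        Per-scan Gaussian noise standard deviation (intensity units).
    seed : int
        RNG seed for the additive noise.
    """

    spectrometer_mhz: float = 400.0
    n_points: int = 65536
    window_ppm: tuple[float, float] = (-0.5, 10.0)
    linewidth_hz: float = 0.7
    n_scans: int = 256
    relaxation_delay_s: float = 90.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        lo, hi = self.window_ppm
        if not lo < hi:
            raise ValueError(f"window_ppm must satisfy low < high, got {self.window_ppm}")
        if self.n_scans < 1:
            raise ValueError(f"n_scans must be >= 1, got {self.n_scans}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.spectrometer_mhz <= 0:
            raise ValueError("spectrometer_mhz must be positive")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be positive")

    @property
    def linewidth_ppm(self) -> float:
        """FWHM converted to ppm."""
        return self.linewidth_hz / self.spectrometer_mhz

    def axis(self) -> np.ndarray:
        """The ppm axis implied by the window and point count."""
        return np.linspace(self.window_ppm[0], self.window_ppm[1], self.n_points)

    def replace(self, **kwargs: Any) -> "AcquisitionParams":
        return replace(self, **kwargs)


@dataclass
class Spectrum:
    """A sampled 1D spectrum: ppm axis, intensities, and metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError(
                f"axis and intensity must be 1D arrays of equal length, "
                f"got {self.ppm.shape} vs {self.intensity.shape}"
            )
        if len(self.ppm) >= 2 and not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.ppm)

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), dict(self.meta))
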