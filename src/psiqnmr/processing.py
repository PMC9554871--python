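"""Spectral processing: baseline correction, window integration, S/N
estimation, and internal-standard normalization.

Quantification here is integration of fixed, named chemical-shift windows
followed by normalization to the internal-standard area; no automatic peak
picking.  The signal-to-noise convention is amplitude / (2 x noise sigma),
with sigma taken from a linearly detrended signal-free region — the
convention most spectrometer software uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectrum import Spectrum

__all__ = [
    "IntegrationWindow",
    "IntegralTable",
    "SNRResult",
    "DEFAULT_WINDOWS",
    "DEFAULT_NOISE_WINDOW",
    "baseline_correct",
    "integrate",
    "integrate_windows",
    "estimate_snr",
    "normalize_to_is",
]


@dataclass(frozen=True)
class IntegrationWindow:
    """A labelled ppm interval to integrate."""

    label: str
    lo_ppm: float
    hi_ppm: float

    def __post_init__(self) -> None:
        if not self.lo_ppm < self.hi_ppm:
            raise ValueError(
                f"window {self.label!r}: lo_ppm must be < hi_ppm "
                f"({self.lo_ppm} >= {self.hi_ppm})"
            )


#: Default integration windows for the hydrolysate spectrum.  The IS window
#: (aromatic 4H of potassium phthalate) and the peak-a and PEG windows are
#: the printed ones; b, c, e windows bracket their shifts, with the peak-e
#: window ending at 1.13 ppm to exclude the 1.15 ppm impurity singlet.
DEFAULT_WINDOWS: dict[str, IntegrationWindow] = {
    "a": IntegrationWindow("a", 2.60, 2.80),
    "b": IntegrationWindow("b", 1.53, 1.73),
    "c": IntegrationWindow("c", 0.52, 0.72),
    "e": IntegrationWindow("e", 1.00, 1.13),
    "peg": IntegrationWindow("peg", 3.70, 3.90),
    "IS": IntegrationWindow("IS", 7.51, 7.64),
}

#: Signal-free region used for noise estimation.
DEFAULT_NOISE_WINDOW = IntegrationWindow("noise", 9.0, 9.5)


@dataclass
class IntegralTable:
    """Raw window areas and their internal-standard-normalized values."""

    raw: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)
    is_label: str | None = None


@dataclass(frozen=True)
class SNRResult:
    label: str
    signal_amplitude: float
    noise_sigma: float
    snr: float


def _window_mask(s: Spectrum, w: IntegrationWindow) -> np.ndarray:
    if w.lo_ppm < s.ppm[0] or w.hi_ppm > s.ppm[-1]:
        raise ValueError(
            f"window {w.label!r} [{w.lo_ppm}, {w.hi_ppm}] lies outside the "
            f"axis [{s.ppm[0]:.4g}, {s.ppm[-1]:.4g}]"
        )
    return (s.ppm >= w.lo_ppm) & (s.ppm <= w.hi_ppm)


def baseline_correct(
    s: Spectrum,
    anchor_regions: list[IntegrationWindow],
    order: int = 1,
) -> Spectrum:
    """Subtract a polynomial baseline anchored on signal-free regions.

    A polynomial of degree ``order`` (default linear, capped at
    n_anchors - 1) is fitted through the (window centre, window median)
    points of the anchor regions and subtracted from the whole spectrum.
    """
    if not anchor_regions:
        raise ValueError("need at least one anchor region")
    xs, ys = [], []
    for w in anchor_regions:
        mask = _window_mask(s, w)
        if not mask.any():
            raise ValueError(f"anchor region {w.label!r} contains no samples")
        xs.append(0.5 * (w.lo_ppm + w.hi_ppm))
        ys.append(float(np.median(s.intensity[mask])))
    deg = min(order, len(xs) - 1)
    coeffs = np.polyfit(xs, ys, deg)
    baseline = np.polyval(coeffs, s.ppm)
    out = s.copy()
    out.intensity = s.intensity - baseline
    out.meta["baseline"] = {"order": deg, "coefficients": coeffs.tolist()}
    return out


def integrate(s: Spectrum, w: IntegrationWindow) -> float:
    """Trapezoidal integral of intensity over [lo_ppm, hi_ppm].

    Window edges falling between samples are handled by linear
    interpolation, which makes integration exactly additive over
    contiguous windows.
    """
    if w.lo_ppm < s.ppm[0] or w.hi_ppm > s.ppm[-1]:
        raise ValueError(
            f"window {w.label!r} [{w.lo_ppm}, {w.hi_ppm}] lies outside the "
            f"axis [{s.ppm[0]:.4g}, {s.ppm[-1]:.4g}]"
        )
    inside = (s.ppm > w.lo_ppm) & (s.ppm < w.hi_ppm)
    x = np.concatenate(([w.lo_ppm], s.ppm[inside], [w.hi_ppm]))
    y = np.concatenate(
        (
            [np.interp(w.lo_ppm, s.ppm, s.intensity)],
            s.intensity[inside],
            [np.interp(w.hi_ppm, s.ppm, s.intensity)],
        )
    )
    return float(np.trapezoid(y, x))


def integrate_windows(
    s: Spectrum, windows: dict[str, IntegrationWindow]
) -> IntegralTable:
    """Integrate every window into a raw :class:`IntegralTable`."""
    return IntegralTable(raw={label: integrate(s, w) for label, w in windows.items()})


def estimate_snr(
    s: Spectrum,
    signal_w: IntegrationWindow,
    noise_w: IntegrationWindow = DEFAULT_NOISE_WINDOW,
) -> SNRResult:
    """Signal-to-noise ratio of a peak.

    The noise region is linearly detrended; sigma is the standard deviation
    of the residual.  The signal amplitude is the maximum over the signal
    window after subtracting the noise-region trend line, and
    snr = amplitude / (2 sigma).
    """
    if not (noise_w.hi_ppm <= signal_w.lo_ppm or noise_w.lo_ppm >= signal_w.hi_ppm):
        raise ValueError("signal and noise windows must be disjoint")
    nmask = _window_mask(s, noise_w)
    xn, yn = s.ppm[nmask], s.intensity[nmask]
    if xn.size < 3:
        raise ValueError("noise window contains too few samples")
    trend = np.polyfit(xn, yn, 1)
    resid = yn - np.polyval(trend, xn)
    sigma = float(np.std(resid))
    if sigma == 0:
        raise ValueError("noise window has zero variance; cannot estimate S/N")
    smask = _window_mask(s, signal_w)
    corrected = s.intensity[smask] - np.polyval(trend, s.ppm[smask])
    amplitude = float(corrected.max())
    return SNRResult(signal_w.label, amplitude, sigma, amplitude / (2.0 * sigma))


def normalize_to_is(areas: IntegralTable, is_label: str = "IS") -> IntegralTable:
    """Divide every raw area by the internal-standard area.

    The normalized internal-standard entry is exactly 1; the operation is
    idempotent and invariant under rescaling of all raw areas.
    """
    if is_label not in areas.raw:
        raise ValueError(f"internal-standard label {is_label!r} not in table")
    is_area = areas.raw[is_label]
    if is_area == 0:
        raise ValueError("internal-standard area is zero; cannot normalize")
    normalized = {label: a / is_area for label, a in areas.raw.items()}
    return IntegralTable(raw=dict(areas.raw), normalized=normalized, is_label=is_label)
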