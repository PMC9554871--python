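"""Forward model for hydrolysate spectra of amine-functionalized porous-silicon
nanoparticles.

The generator renders each assigned multiplet as a sum of Lorentzian lines
whose total area is proportional to

    n_protons x molar amount (umol) x n_scans x (1 - exp(-d / T1)),

with d the inter-scan relaxation delay, so partial longitudinal relaxation
attenuates under-relaxed peaks exactly as in a real quantitative experiment.
White Gaussian noise of standard deviation ``noise_sigma * sqrt(n_scans)`` is
added in the frequency domain, which makes the signal-to-noise ratio grow as
sqrt(n_scans).  Everything is deterministic for a fixed seed.

The default assignment set emulates the alkaline hydrolysate of
(3-aminopropyl)triethoxysilane-modified particles: the alpha-methylene
"complex pattern" (two triplets in 2.6-2.8 ppm), beta/gamma methylenes at
1.63/0.62 ppm, residual ethoxy CH2/CH3 at 3.66/1.09 ppm, an impurity singlet
at 1.15 ppm, the aromatic 4H of the potassium phthalate internal standard in
7.51-7.64 ppm, and optionally the PEG repeat-unit peak in 3.70-3.90 ppm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .relaxometry import InversionRecoverySeries, mz_recovery_fraction
from .spectrum import AcquisitionParams, Spectrum

__all__ = [
    "MultipletAssignment",
    "SpeciesComposition",
    "default_assignments",
    "render_spectrum",
    "generate_calibration_series",
    "generate_pegylation_series",
    "generate_inversion_recovery",
    "internal_standard_umol",
    "noise_sigma_for_snr",
    "MONOPOTASSIUM_PHTHALATE_G_MOL",
]

#: Molar mass of the monopotassium phthalate internal standard (g/mol).
MONOPOTASSIUM_PHTHALATE_G_MOL = 204.22

_PATTERN_WEIGHTS = {
    "singlet": (1.0,),
    "triplet": (0.25, 0.5, 0.25),
    "quartet": (0.125, 0.375, 0.375, 0.125),
}

_VALID_SPECIES = {"APS-residue", "PEG", "internal_standard", "impurity"}


@dataclass(frozen=True)
class MultipletAssignment:
    """A named resonance of one species.

    ``pattern`` is one of singlet / triplet / quartet / complex.  A complex
    pattern is a weighted sum of sub-multiplets given by ``components`` as
    ``(center_ppm, weight)`` pairs; each component is itself split by
    ``j_hz`` (triplet if j_hz > 0, singlet otherwise).  Component weights
    are normalized so the multiplet always integrates to n_protons x amount.
    """

    label: str
    center_ppm: float
    pattern: str
    j_hz: float
    n_protons: float
    species: str
    t1_s: float
    components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.pattern not in ("singlet", "triplet", "quartet", "complex"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "complex" and not self.components:
            raise ValueError("complex pattern requires components")
        if self.n_protons <= 0:
            raise ValueError(f"n_protons must be positive, got {self.n_protons}")
        if self.j_hz < 0:
            raise ValueError(f"j_hz must be >= 0, got {self.j_hz}")
        if self.t1_s <= 0:
            raise ValueError(f"t1_s must be positive, got {self.t1_s}")
        if self.species not in _VALID_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")

    def line_positions(self, spectrometer_mhz: float) -> list[tuple[float, float]]:
        """Expand into (center_ppm, fractional_weight) Lorentzian lines."""
        j_ppm = self.j_hz / spectrometer_mhz
        if self.pattern == "complex":
            total = sum(w for _, w in self.components)
            lines: list[tuple[float, float]] = []
            sub = _PATTERN_WEIGHTS["triplet"] if self.j_hz > 0 else _PATTERN_WEIGHTS["singlet"]
            offs = np.arange(len(sub)) - (len(sub) - 1) / 2.0
            for center, weight in self.components:
                for o, sw in zip(offs, sub):
                    lines.append((center + o * j_ppm, sw * weight / total))
            return lines
        weights = _PATTERN_WEIGHTS[self.pattern]
        offsets = np.arange(len(weights)) - (len(weights) - 1) / 2.0
        return [(self.center_ppm + o * j_ppm, w) for o, w in zip(offsets, weights)]


@dataclass(frozen=True)
class SpeciesComposition:
    """Planted ground truth the pipeline must recover.

    amine_loading_umol_per_mg : surface amine content per mg of particles.
    ethoxy_per_amine          : residual un-hydrolyzed ethoxy groups per
                                silane residue (0-3).
    peg_umol_per_mg           : conjugated PEG per mg of particles.
    impurity_scale            : molar amount of the 1.15 ppm impurity
                                singlet per mg of particles.
    """

    amine_loading_umol_per_mg: float = 0.294
    ethoxy_per_amine: float = 1.0
    peg_umol_per_mg: float = 0.0
    impurity_scale: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "amine_loading_umol_per_mg",
            "ethoxy_per_amine",
            "peg_umol_per_mg",
            "impurity_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_assignments(
    include_peg: bool = False,
    *,
    ethoxy_per_amine: float = 1.0,
    peg_protons: float = 452.0,
    d_center_ppm: float = 3.66,
    alpha_components: Sequence[tuple[float, float]] = ((2.65, 0.5), (2.75, 0.5)),
) -> list[MultipletAssignment]:
    """Assignment set for the hydrolysate spectrum.

    Peak a (alpha-CH2 next to the amine) is a complex pattern of two
    triplets in 2.6-2.8 ppm; b and c are the beta/gamma methylenes; d and e
    are the residual ethoxy CH2 (quartet) and CH3 (triplet), whose per-residue
    proton counts scale with ``ethoxy_per_amine``; the impurity is a sharp
    singlet at 1.15 ppm; the internal standard contributes 4 aromatic protons
    in 7.51-7.64 ppm.  With ``include_peg`` the PEG repeat-unit resonance
    (default 452 protons per 5 kDa chain) is added at 3.80 ppm, overlapping
    the ethoxy CH2 window.
    """
    t1 = _DEFAULT_T1
    out = [
        MultipletAssignment(
            "a", 2.70, "complex", 7.0, 2, "APS-residue", t1["a"],
            components=tuple(alpha_components),
        ),
        MultipletAssignment("b", 1.63, "triplet", 7.0, 2, "APS-residue", t1["b"]),
        MultipletAssignment("c", 0.62, "triplet", 7.0, 2, "APS-residue", t1["c"]),
        MultipletAssignment("impurity", 1.15, "singlet", 0.0, 1, "impurity", 3.0),
        MultipletAssignment(
            "IS", 7.575, "complex", 0.0, 4, "internal_standard", t1["internal_standard"],
            components=((7.54, 0.5), (7.61, 0.5)),
        ),
    ]
    if ethoxy_per_amine > 0:
        out.insert(
            3,
            MultipletAssignment(
                "d", d_center_ppm, "quartet", 7.0, 2 * ethoxy_per_amine,
                "APS-residue", t1["d"],
            ),
        )
        out.insert(
            4,
            MultipletAssignment(
                "e", 1.09, "triplet", 7.0, 3 * ethoxy_per_amine, "APS-residue", t1["e"],
            ),
        )
    if include_peg:
        out.append(
            MultipletAssignment("f", 3.80, "singlet", 0.0, peg_protons, "PEG", 1.0)
        )
    return out


# Longitudinal relaxation times (s) used for partial-recovery attenuation;
# short for the propyl backbone, longer for ethoxy and the aromatic standard.
_DEFAULT_T1 = {
    "internal_standard": 5.08,
    "a": 1.63,
    "b": 1.57,
    "c": 1.08,
    "d": 6.51,
    "e": 6.11,
}


def _lorentzian(x: np.ndarray, x0: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian."""
    return (hwhm / math.pi) / ((x - x0) ** 2 + hwhm**2)


def render_spectrum(
    assignments: Sequence[MultipletAssignment],
    amounts_umol: dict[str, float],
    acq: AcquisitionParams,
) -> Spectrum:
    """Render a spectrum from assignments and per-species molar amounts.

    ``amounts_umol`` maps species name to the molar amount in the tube
    (umol).  Every species referenced by an assignment must be present.
    """
    for a in assignments:
        if a.species not in amounts_umol:
            raise ValueError(
                f"no molar amount supplied for species {a.species!r} "
                f"(required by assignment {a.label!r})"
            )
    x = acq.axis()
    y = np.zeros_like(x)
    hwhm = acq.linewidth_ppm / 2.0
    lo, hi = acq.window_ppm
    for a in assignments:
        if not lo <= a.center_ppm <= hi:
            raise ValueError(
                f"assignment {a.label!r} at {a.center_ppm} ppm lies outside "
                f"the simulated window {acq.window_ppm}"
            )
        amount = amounts_umol[a.species]
        if amount == 0:
            continue
        recovery = mz_recovery_fraction(acq.relaxation_delay_s, a.t1_s)
        area = a.n_protons * amount * acq.n_scans * recovery
        for center, w in a.line_positions(acq.spectrometer_mhz):
            y += (w * area) * _lorentzian(x, center, hwhm)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        y = y + rng.normal(0.0, acq.noise_sigma * math.sqrt(acq.n_scans), x.size)
    meta = {
        "acquisition": acq,
        "species_amounts_umol": dict(amounts_umol),
    }
    return Spectrum(x, y, meta)


def internal_standard_umol(
    mass_mg: float, molar_mass_g_mol: float = MONOPOTASSIUM_PHTHALATE_G_MOL
) -> float:
    """Moles (umol) of internal standard from its weighed mass (mg)."""
    if mass_mg <= 0:
        raise ValueError("internal-standard mass must be positive")
    return 1000.0 * mass_mg / molar_mass_g_mol


def _amounts_for_mass(
    composition: SpeciesComposition, mass_mg: float, is_umol: float
) -> dict[str, float]:
    return {
        "APS-residue": composition.amine_loading_umol_per_mg * mass_mg,
        "PEG": composition.peg_umol_per_mg * mass_mg,
        "impurity": composition.impurity_scale * mass_mg,
        "internal_standard": is_umol,
    }


def generate_calibration_series(
    masses_mg: Sequence[float],
    composition: SpeciesComposition,
    is_mass_mg: float,
    acq: AcquisitionParams,
    *,
    is_molar_mass: float = MONOPOTASSIUM_PHTHALATE_G_MOL,
    assignments: Sequence[MultipletAssignment] | None = None,
) -> list[tuple[float, Spectrum]]:
    """Mass-calibration series: analyte scales with mass, standard is fixed.

    One spectrum per sample mass; all analyte amounts (amines, ethoxy,
    impurity) scale linearly with the weighed particle mass while the
    internal-standard amount is identical across the series, mirroring a
    dilution series prepared from one standard stock.
    """
    if len(masses_mg) == 0:
        raise ValueError("empty mass list")
    if any(m <= 0 for m in masses_mg):
        raise ValueError("masses must be positive")
    if assignments is None:
        assignments = default_assignments(
            include_peg=composition.peg_umol_per_mg > 0,
            ethoxy_per_amine=composition.ethoxy_per_amine,
        )
    is_umol = internal_standard_umol(is_mass_mg, is_molar_mass)
    series = []
    for i, mass in enumerate(masses_mg):
        acq_i = acq.replace(seed=acq.seed + i)
        amounts = _amounts_for_mass(composition, mass, is_umol)
        series.append((mass, render_spectrum(assignments, amounts, acq_i)))
    return series


def generate_pegylation_series(
    feed_ratios: Sequence[float],
    peg_loadings_umol_per_mg: Sequence[float],
    composition: SpeciesComposition,
    is_mass_mg: float,
    acq: AcquisitionParams,
    *,
    particle_mass_mg: float = 1.0,
    peg_protons: float = 452.0,
    is_molar_mass: float = MONOPOTASSIUM_PHTHALATE_G_MOL,
) -> list[tuple[float, Spectrum]]:
    """PEGylation series: one hydrolysate spectrum per feeding ratio.

    The ethoxy CH2 quartet is centred at 3.78 ppm here: in the alkaline
    hydrolysate it sits inside the 3.70-3.90 ppm PEG window, which is the
    overlap the stoichiometric deconvolution corrects for.
    """
    if len(feed_ratios) != len(peg_loadings_umol_per_mg):
        raise ValueError("feed_ratios and peg_loadings must have equal length")
    is_umol = internal_standard_umol(is_mass_mg, is_molar_mass)
    out = []
    for i, (ratio, peg_loading) in enumerate(zip(feed_ratios, peg_loadings_umol_per_mg)):
        comp_i = replace(composition, peg_umol_per_mg=peg_loading)
        assignments = default_assignments(
            include_peg=True,
            ethoxy_per_amine=comp_i.ethoxy_per_amine,
            peg_protons=peg_protons,
            d_center_ppm=3.78,
        )
        acq_i = acq.replace(seed=acq.seed + i)
        amounts = _amounts_for_mass(comp_i, particle_mass_mg, is_umol)
        out.append((ratio, render_spectrum(assignments, amounts, acq_i)))
    return out


def generate_inversion_recovery(
    fit_params: tuple[float, float, float],
    delays_s: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> InversionRecoverySeries:
    """Synthesize an inversion-recovery series y = B + F exp(-x G) + noise."""
    delays = np.asarray(delays_s, dtype=float)
    if delays.size == 0:
        raise ValueError("delays must be non-empty")
    if np.any(delays <= 0):
        raise ValueError("delays must be strictly positive")
    b, f, g = fit_params
    y = b + f * np.exp(-delays * g)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, delays.size)
    order = np.argsort(delays)
    return InversionRecoverySeries(delays[order], y[order], label=label)


def noise_sigma_for_snr(
    target_snr: float,
    assignments: Sequence[MultipletAssignment],
    amounts_umol: dict[str, float],
    acq: AcquisitionParams,
    signal_window: tuple[float, float] = (2.6, 2.8),
) -> float:
    """Per-scan noise sigma that puts the tallest line of ``signal_window``
    at the requested signal-to-noise ratio (amplitude / 2 sigma convention)
    after scan averaging."""
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    clean = render_spectrum(assignments, amounts_umol, acq.replace(noise_sigma=0.0))
    mask = (clean.ppm >= signal_window[0]) & (clean.ppm <= signal_window[1])
    amplitude = float(clean.intensity[mask].max())
    sigma_total = amplitude / (2.0 * target_snr)
    return sigma_total / math.sqrt(acq.n_scans)
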