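"""Internal-standard quantification of surface functional groups.

The qNMR relation: with peak areas normalized to the internal standard,

    n_analyte = (A_analyte / H_analyte) * H_IS * n_IS,

where H are protons per molecule contributing to each integrated multiplet
and n_IS the moles of standard in the tube.  Amine loading comes either
from a single spectrum or from the slope of a mass-calibration line
(normalized peak-a area vs. weighed particle mass).  PEG loading requires a
stoichiometric overlap correction first: the 3.70-3.90 ppm window contains
both the PEG repeat-unit peak and the ethoxy CH2 quartet, whose area is
deduced from the ethoxy CH3 peak via the 2:3 proton ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .processing import (
    DEFAULT_WINDOWS,
    IntegralTable,
    IntegrationWindow,
    integrate_windows,
    normalize_to_is,
)
from .spectrum import Spectrum

__all__ = [
    "InternalStandard",
    "QuantResult",
    "CalibrationResult",
    "ConjugationMetrics",
    "NITROGEN_G_MOL",
    "quantify_by_internal_standard",
    "fit_mass_calibration",
    "elemental_to_loading",
    "deconvolve_peg_area",
    "peg_metrics",
    "count_rate_ratio",
    "amine_loading_from_spectrum",
    "peg_loading_from_spectrum",
]

NITROGEN_G_MOL = 14.007

#: Protons of the ethoxy CH2 (d) and CH3 (e) per ethoxy group; their 2:3
#: ratio drives the overlap correction.
H_ETHOXY_CH2 = 2
H_ETHOXY_CH3 = 3


@dataclass(frozen=True)
class InternalStandard:
    """The quantification anchor: a weighed amount of a known compound.

    Default identity is monopotassium phthalate, quantified on its 4
    aromatic protons.
    """

    name: str = "monopotassium phthalate"
    molar_mass: float = 204.22
    n_protons: int = 4
    mass_mg: float = 0.4

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.mass_mg <= 0:
            raise ValueError("molar mass and mass must be positive")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")

    @property
    def moles_umol(self) -> float:
        return 1000.0 * self.mass_mg / self.molar_mass


@dataclass(frozen=True)
class QuantResult:
    analyte_label: str
    moles_umol: float
    loading_umol_per_mg: float
    sample_mass_mg: float


@dataclass(frozen=True)
class CalibrationResult:
    """OLS line through (mass, normalized area) with the implied loading."""

    slope: float
    intercept: float
    r_squared: float
    masses_mg: tuple[float, ...]
    areas: tuple[float, ...]
    loading_umol_per_mg: float
    loading_umol_per_mg_mean: float


@dataclass(frozen=True)
class ConjugationMetrics:
    """Derived PEG-conjugation metrics for one feeding ratio.

    feed_ratio              : mol PEG fed per mol surface amine.
    n_peg_umol_per_mg       : conjugated PEG per mg of particles.
    pct_amine_substituted   : 100 x N_PEG / N_NH2.
    pct_reaction_efficiency : 100 x N_PEG / (feed_ratio x N_NH2).
    pct_weight              : 100 x PEG mass / particle mass.
    """

    feed_ratio: float
    n_peg_umol_per_mg: float
    pct_amine_substituted: float
    pct_reaction_efficiency: float
    pct_weight: float


def quantify_by_internal_standard(
    norm_area_analyte: float, h_analyte: float, istd: InternalStandard
) -> float:
    """Moles (umol) of analyte from its IS-normalized area."""
    if h_analyte <= 0:
        raise ValueError("h_analyte must be positive")
    if norm_area_analyte < 0:
        raise ValueError("normalized area must be >= 0")
    return norm_area_analyte * (istd.n_protons / h_analyte) * istd.moles_umol


def fit_mass_calibration(
    masses_mg: Sequence[float],
    norm_areas: Sequence[float],
    h_analyte: float = 2,
    istd: InternalStandard = InternalStandard(),
) -> CalibrationResult:
    """Fit the mass-calibration line and derive the per-mg loading.

    Ordinary least squares with a free intercept; the loading estimate
    converts the slope (normalized area per mg) through the internal
    standard.  A second estimator — the mean of per-mass loadings — is
    reported alongside.
    """
    masses = np.asarray(masses_mg, dtype=float)
    areas = np.asarray(norm_areas, dtype=float)
    if masses.size != areas.size:
        raise ValueError("masses and areas must have equal length")
    if np.unique(masses).size < 3:
        raise ValueError("need at least 3 distinct masses")
    fit = stats.linregress(masses, areas)
    loading = quantify_by_internal_standard(fit.slope, h_analyte, istd)
    per_mass = [
        quantify_by_internal_standard(a, h_analyte, istd) / m
        for m, a in zip(masses, areas)
    ]
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        masses_mg=tuple(masses),
        areas=tuple(areas),
        loading_umol_per_mg=loading,
        loading_umol_per_mg_mean=float(np.mean(per_mass)),
    )


def elemental_to_loading(nitrogen_wt_pct: float, n_atoms_per_group: int = 1) -> float:
    """Amine loading (umol/mg) implied by a nitrogen weight percentage.

    loading = (wt% / 100) * 1000 / (14.007 * n_atoms_per_group); one
    nitrogen per amine by default.
    """
    if not 0 <= nitrogen_wt_pct <= 100:
        raise ValueError(f"weight percent must be in [0, 100], got {nitrogen_wt_pct}")
    if n_atoms_per_group < 1:
        raise ValueError("n_atoms_per_group must be >= 1")
    return (nitrogen_wt_pct / 100.0) * 1000.0 / (NITROGEN_G_MOL * n_atoms_per_group)


def deconvolve_peg_area(
    area_3p70_3p90: float,
    area_peak_e: float,
    h_d: float = H_ETHOXY_CH2,
    h_e: float = H_ETHOXY_CH3,
) -> float:
    """PEG area after removing the ethoxy CH2 contribution.

    A_f = A_window - (h_d / h_e) x A_e; with the 2:3 default this subtracts
    two thirds of the ethoxy CH3 area.  A negative result (possible under
    noise) is clipped to zero with a warning.
    """
    if area_3p70_3p90 < 0 or area_peak_e < 0:
        raise ValueError("areas must be >= 0")
    a_f = area_3p70_3p90 - (h_d / h_e) * area_peak_e
    if a_f < 0:
        warnings.warn(
            f"deconvolved PEG area is negative ({a_f:.3g}); clipping to 0",
            stacklevel=2,
        )
        return 0.0
    return a_f


def peg_metrics(
    n_peg_umol: float,
    n_nh2_umol: float,
    feed_ratio: float,
    m_peg_da: float = 5000.0,
    particle_mass_mg: float = 1.0,
) -> ConjugationMetrics:
    """Conjugation metrics for one PEG feeding ratio.

    The weight percentage uses the PEG mass (n_peg_umol x m_peg_da / 1000,
    in mg) over the particle mass.
    """
    if n_nh2_umol <= 0:
        raise ValueError("n_nh2_umol must be positive")
    if feed_ratio <= 0:
        raise ValueError("feed_ratio must be positive")
    if particle_mass_mg <= 0:
        raise ValueError("particle_mass_mg must be positive")
    if n_peg_umol < 0:
        raise ValueError("n_peg_umol must be >= 0")
    pct_sub = 100.0 * n_peg_umol / n_nh2_umol
    pct_eff = pct_sub / feed_ratio
    w_peg_mg = n_peg_umol * m_peg_da / 1000.0
    pct_weight = 100.0 * w_peg_mg / particle_mass_mg
    return ConjugationMetrics(
        feed_ratio=feed_ratio,
        n_peg_umol_per_mg=n_peg_umol / particle_mass_mg,
        pct_amine_substituted=pct_sub,
        pct_reaction_efficiency=pct_eff,
        pct_weight=pct_weight,
    )


def count_rate_ratio(conc_ratio: float, radius_ratio: float) -> float:
    """Relative light-scattering derived count rate, proportional to
    concentration x radius^6; tracks particle dissolution."""
    if conc_ratio <= 0 or radius_ratio <= 0:
        raise ValueError("ratios must be positive")
    return conc_ratio * radius_ratio**6


# -- spectrum-level drivers ---------------------------------------------------


def amine_loading_from_spectrum(
    spectrum: Spectrum,
    sample_mass_mg: float,
    istd: InternalStandard = InternalStandard(),
    windows: dict[str, IntegrationWindow] | None = None,
    h_analyte: float = 2,
) -> QuantResult:
    """Amine loading from one hydrolysate spectrum via the peak-a window."""
    if sample_mass_mg <= 0:
        raise ValueError("sample_mass_mg must be positive")
    windows = windows or DEFAULT_WINDOWS
    table = normalize_to_is(integrate_windows(spectrum, windows), "IS")
    moles = quantify_by_internal_standard(table.normalized["a"], h_analyte, istd)
    return QuantResult("amine", moles, moles / sample_mass_mg, sample_mass_mg)


def peg_loading_from_spectrum(
    spectrum: Spectrum,
    sample_mass_mg: float,
    istd: InternalStandard = InternalStandard(),
    windows: dict[str, IntegrationWindow] | None = None,
    h_peg: float = 452.0,
) -> QuantResult:
    """Conjugated-PEG loading from one spectrum.

    Integrates the 3.70-3.90 ppm window and the ethoxy CH3 window,
    applies the 2:3 overlap correction, then converts through the
    internal standard using ``h_peg`` repeat-unit protons per chain.
    """
    if sample_mass_mg <= 0:
        raise ValueError("sample_mass_mg must be positive")
    windows = windows or DEFAULT_WINDOWS
    table = normalize_to_is(integrate_windows(spectrum, windows), "IS")
    a_f = deconvolve_peg_area(table.normalized["peg"], table.normalized["e"])
    moles = quantify_by_internal_standard(a_f, h_peg, istd)
    return QuantResult("PEG", moles, moles / sample_mass_mg, sample_mass_mg)


def integral_table_for(
    spectrum: Spectrum, windows: dict[str, IntegrationWindow] | None = None
) -> IntegralTable:
    """Convenience: integrate the default windows and normalize to the IS."""
    return normalize_to_is(integrate_windows(spectrum, windows or DEFAULT_WINDOWS), "IS")
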