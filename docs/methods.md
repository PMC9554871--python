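# Methods

## The measurement model

Surface groups on aminosilane-modified porous-silicon particles are not
directly observable by solution NMR: bound to the solid they are immobile
and their lines vanish into the baseline. Alkaline hydrolysis (0.1 M NaOD)
dissolves the silicon matrix and releases the organosilane residues, whose
spectrum is then sharp enough for quantitative integration. The package
implements the quantification on top of the standard qNMR identity: the
integrated area of a multiplet is proportional to (protons per molecule) ×
(molar amount), with the proportionality constant eliminated by normalizing
to an internal standard of known amount,

    n_analyte = (A_analyte / H_analyte) · H_IS · n_IS .

The standard is monopotassium phthalate (204.22 g/mol; the dipotassium salt,
242.31 g/mol, is supported through the configurable molar mass), quantified
on its 4 aromatic protons in 7.51–7.64 ppm. 0.4 mg of standard corresponds
to 1.959 μmol.

Amine loading uses the α-methylene window 2.6–2.8 ppm (2H per residue),
either from a single spectrum or as the slope of the normalized-area vs.
sample-mass line (ordinary least squares with a free intercept; the free
intercept makes the estimator robust to any constant background, and the
mean of per-mass estimates is reported as a second estimator). An elemental
cross-check converts a nitrogen weight percentage to μmol/mg via
`(wt%/100)·1000/14.007` per nitrogen atom.

PEG conjugation is read from the repeat-unit resonance in 3.70–3.90 ppm.
That window also contains the residual ethoxy CH₂ quartet, so the ethoxy
contribution is removed stoichiometrically using the CH₃ triplet of the same
ethoxy group (window 1.00–1.13 ppm) and the fixed 2:3 proton ratio:
`A_PEG = A_window − (2/3)·A_CH₃`. Negative corrected areas — possible under
noise when little PEG is present — clip to zero with a warning rather than
an error. Moles of PEG use a configurable proton count per chain, default
452 = 4 × round(5000/44.05) repeat-unit protons for 5 kDa methoxy-PEG; the
end-group accounting of a real lot is unknown, which is why it is a
parameter. The derived conjugation metrics for a feeding ratio r (mol PEG
fed per mol amine) are: percent of amines substituted, 100·N_PEG/N_NH₂;
reaction efficiency, the same divided by r; and weight percent,
100·(N_PEG·M_PEG)/particle mass, with the particle mass alone in the
denominator (the convention that reproduces the reference table's
arithmetic).

## Relaxometry

Inversion-recovery integrals are fitted to the three-parameter exponential
`y = B + F·exp(−xG)` (F < 0 for inversion recovery), with `T1 ≡ 1/G` of the
fitted rate. Fitting is bounded nonlinear least squares (lmfit) with
G ∈ [1e−4, 1e3] s⁻¹, initialized from the data (B₀ = y at the longest
delay, F₀ = y(shortest) − B₀, G₀ = ln 2 / the half-recovery delay) and
restarted from G₀×0.1 and G₀×10 if the optimizer reports failure;
non-convergence is returned as a flag, never silently. The reference
parameter set bundled with the package spans rates from 0.06 s⁻¹ (residual
solvent, T1 = 16.95 s) to 0.92 s⁻¹, and the 13-delay schedule runs from
0.01 to 50 s. One tabulated delay in the source experiment reads 0.125 s
between 0.55 and 2.20 s; the schedule here uses 1.25 s, the value that
restores monotonic spacing, and the generator accepts any user list.

The planning rule is `delay = 5 × max(T1)`, which recovers
1 − e⁻⁵ = 99.33% of the equilibrium magnetization; for the reference T1 set
this gives 84.75 s, consistent with the 90 s used in practice. The forward
model applies exactly this attenuation, `1 − exp(−delay/T1)` per peak, so
under-relaxed acquisition biases synthetic areas the same way it biases
real ones.

## The synthetic generator: what it emulates, what it does not

Each multiplet is a sum of Lorentzian lines (the natural NMR lineshape, and
the choice with an exact arctan window integral to test against). Patterns
are singlet, 1:2:1 triplet, 1:3:3:1 quartet, or "complex" — a weighted set
of sub-multiplets used for the α-methylene region, modeled as two triplets
at 2.65/2.75 ppm with equal weight (the split reflects mixed protonation /
incomplete hydrolysis of the residues; the true substructure is not
resolvable from the source data, so centers and weights are configurable).
J couplings default to 7 Hz and are converted to ppm via the spectrometer
frequency (default 400 MHz, configurable — the source instrument's field is
unstated). Noise is white Gaussian added in the frequency domain with
standard deviation σ·√(n_scans) against signal ∝ n_scans, giving the
√n_scans S/N law; there is no time-domain FID simulation, phase error,
baseline roll, solvent peak, or shimming artifact. Consequences: passing
tests demonstrate correctness of the integration/normalization/conversion
chain and its statistical behavior under white noise, not robustness to
phase/baseline pathologies of real spectra (the baseline-correction stage
exists for those, but is exercised only on synthetic ramps).

Default linewidth is 0.7 Hz FWHM, a well-shimmed solution value, chosen at
design time from a tail-capture analysis: Lorentzian tails are heavy, and
the fixed integration windows capture 98–99.5% of each multiplet. Because
every quantification is a ratio to the internal standard, these losses
largely cancel (net bias ~0.3–0.7% across the default windows), which is
why window truncation is not tail-corrected. The default axis is 65,536
points over −0.5 to 10 ppm (file fixtures use 32,768), keeping the grid
several times finer than the half-width so trapezoidal integration is
accurate to ≪1%.

In the PEGylation generator the ethoxy CH₂ quartet is centred at 3.78 ppm —
inside the PEG window — emulating the alkaline-solvent shift that makes the
two peaks overlap in hydrolysates (the overlap is the premise of the
stoichiometric correction); pure-silane assignments keep the CH₂ at its
3.66 ppm literature shift. An impurity singlet at 1.15 ppm is planted next
to the ethoxy CH₃ peak, and the CH₃ window deliberately stops at 1.13 ppm
to exclude it; its default amount (0.05 μmol per mg) leaks ≲0.1% of the CH₃
area into the window through its tail.

Default planted ground truth: 0.294 μmol amines per mg, one residual ethoxy
group per silane residue (incomplete condensation), and PEG loadings of
0.010–0.025 μmol/mg across feeding ratios 0.1–2.

## Numerical conventions and edge cases

- **Integration** is trapezoidal with linear interpolation at window edges,
  which makes it exactly additive over adjacent windows.
- **S/N** is amplitude/(2σ), with σ the standard deviation of a linearly
  detrended signal-free region (default 9.0–9.5 ppm) and the amplitude the
  trend-corrected maximum of the signal window — the common
  spectrometer-software convention; a zero-variance noise region is an
  error, not an S/N of infinity.
- **Baseline correction** fits a polynomial (default linear, degree capped
  at n_anchors − 1) through the medians of signal-free anchor windows.
- **Normalization** to the internal standard is idempotent and invariant to
  rescaling all raw areas; a zero or missing standard area is an error.
- **Determinism**: every stochastic step takes an explicit seed; identical
  inputs, configuration, and seed reproduce bit-identical arrays and
  report files (logs carry input hashes, no timestamps).
- The bundled reference (B, F, G, T1) rows are mutually consistent under
  two-decimal truncation of 1/T1 for six of seven peaks; the solvent row is
  consistent under rounding instead. This is recorded as a data-provenance
  check in the tests, not a property of the algorithm.

## Problem sizes

Monte-Carlo claims (S/N ∝ √scans within 10%, integral CV ≤ 5% at S/N ≥ 20,
median calibration R² ≥ 0.99 at S/N ≈ 240, parameter recovery within 5% at
S/N ≈ 50) are evaluated over 20 seeds each on full-resolution spectra; the
package's defaults make this a few seconds of compute, and the estimates
are stable well below the asserted tolerances at that replication level.

## Known limitations

- No FID/time-domain simulation, phasing, apodization, or 2D experiments.
- Fixed-window integration only; no automatic peak picking or lineshape
  deconvolution beyond the stoichiometric ethoxy correction.
- The PEG proton count per chain (hence its molar conversion) is nominal
  for a 5 kDa lot; real lots need the vendor's end-group data.
- The elemental cross-check converts composition to loading but cannot by
  itself arbitrate hydrolysis completeness — in practice the NMR route can
  read low if the matrix does not fully dissolve, so disagreement between
  the two routes is informative, not an error of either.
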