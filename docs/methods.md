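# Methods

This note records the model choices behind `gcrdose`, the parameters that
matter, and what the pipeline can and cannot be expected to reproduce.

## Source model

Each element Z = 1–26 (most abundant stable isotope) carries a local
interstellar spectrum that is a pure power law in momentum per nucleon,
J_LIS(E) = N·a_i·p(E)^(−γ) with γ = 2.78, modulated by the force-field
approximation

    J(E, φ) = J_LIS(E + (Z/A)φ) · p(E)² / p(E + (Z/A)φ)² ,

evaluated on 200 log-spaced points over 1 MeV/n – 100 GeV/n. The default
modulation potential is φ = 450 MV, a representative solar-minimum value;
solar minimum is the worst case for GCR exposure and is the regime all
defaults target. Zero modulation returns the LIS identically, and
increasing φ strictly decreases the flux at every energy — both are tested
properties. The modulated spectra peak at 130–260 MeV/n depending on Z/A.

Two calibrations pin the free constants, both performed once through the
package's own dose estimator and then frozen:

* **Relative abundances a_i.** Helium is set by the canonical particle
  composition (87 % protons : 13 % heavier, tested at ±3 percentage
  points). The Z ≥ 3 scales are chosen so the per-element free-space
  absorbed-dose contributions reproduce the standard elemental ranking
  (H > He > O > C ≈ Fe, even-Z enhancement through the Mg/Si and Fe
  groups). A consequence of pinning He by particle number rather than by
  dose is that the He dose share (~54 mGy/yr) is higher than
  coefficient-based reference tables (~33 mGy/yr); the ranking is
  unaffected.
* **Absolute normalization N.** Chosen so the free-space total absorbed
  dose rate in the 30-cm slab phantom equals 164 mGy/yr (0.45 mGy/day),
  the quiet-time interplanetary GCR dose rate observed by deep-space
  cruise dosimetry. This anchors the pipeline to a measured quantity
  rather than to any unpublished model coefficient.

## Stopping power and ranges

Unrestricted electronic stopping uses the Bethe formula with the Barkas
effective-charge parameterization Z\* = Z(1 − exp(−125βZ^(−2/3))); shell,
density-effect and higher-order corrections are omitted. The validity
floor is 0.1 MeV/n; CSDA ranges below it are extended with an R ∝ E^1.8
power law (logged) so slowing-down bookkeeping has no gap. Mean excitation
energies come from Bragg additivity over standard elemental I-values
(tissue: 69.3 eV). Against published proton tables the minimum-ionizing
LET in unit-density tissue lands at 0.205 keV/µm (benchmark band
0.18–0.28), and the LET(E) of every ion has a single minimum between
0.5 and 5 GeV/n.

Materials: ICRU four-element tissue (H/C/N/O = 10.1/11.1/2.6/76.2 % by
mass, ρ = 1), aluminum (2.70 g/cm³), polyethylene (C₂H₄)ₙ (0.94 g/cm³),
and CF/PEEK CFRP modeled as 60 % carbon fiber / 40 % PEEK (C₁₉H₁₂O₃) by
mass at 1.55 g/cm³. The laminate split and densities are configurable;
datasheet-exact CFRP fractions are not public, so the 60/40 aerospace
typical is used.

## Energy→LET transform

LET(E) is non-monotone, so the fluence density maps onto LET through two
branches whose Jacobian diverges at the minimum-ionizing point. Rather
than inverting branches explicitly, each energy cell (subdivided 12× in
log space) deposits its particle fluence uniformly over the LET interval
spanned by its endpoints onto a 300-bin log grid over 0.05–3000 keV/µm.
This mass-preserving rebinning conserves particle number by construction;
the only loss is clipping of LET values outside the grid (the sub-3 MeV/n
tail of Fe), below 0.5 % for every default spectrum. The spectral mode is
reported as the bin-midpoint of maximum differential flux. Fe tracks near
the end of range exceed the 3000 keV/µm grid cap; their dose is kept in
the top bin, which slightly overstates the quality factor of a tiny dose
fraction.

## Biological weights

The ICRP-60 quality factor is implemented with both breakpoints assigned
to the middle branch: QF(10) = 1.0 keeps the function continuous, while
QF(100) = 29.8 versus 30.0 from the high-LET branch is an inherent 0.7 %
ambiguity of the published piecewise form (the supremum of the curve just
above 100 keV/µm is 30.0).

The track-structure RBE referenced to acute γ-rays is

    RBE = (1 − P) + 6.24 σ₀ P / (α_γ L),   P = (1 − exp(−Z*²/κβ²))^m .

As commonly typeset, the ion-kill term appears without the P weight; that
form diverges as L → 0 and contradicts the model's gamma-like limit, so
the P-weighted form is the default and the literal form is available
behind `strict_literal=True`. The factor 6.24 converts fluence·σ₀/α_γ to
dose at unit density (1 Gy = 6.24 keV/µm per µm³ of unit-density matter).

The four constants (σ₀, α_γ, m, κ) are endpoint-specific experimental
fits and are deliberately not defaulted in code. The shipped
`lymphocyte-simple-exchange` set (σ₀ = 6.0 µm², α_γ = 0.055 Gy⁻¹, m = 3,
κ = 250) contains placeholder values chosen for order-of-magnitude realism
for chromosome simple exchanges in human lymphocytes; RBE-weighted results
are therefore structurally meaningful (limits, orderings, reduction
trends) but not absolutely calibrated until the published fit is
substituted.

## Dose estimators

The default phantom is a 30-cm (30 g/cm²) unit-density tissue slab. Each
spectrum is range-shifted through 0.5 g/cm² sublayers; the energy
deposited per sublayer is binned by the local LET (geometric-mean energy
of the step; particles stopping within a step deposit their remaining
energy at the LET of half their entrance energy) and averaged over the
slab mass. This restores the body self-shielding that whole-body fluence-
to-dose coefficients encode: sub-100 MeV/n particles stop in the first
centimeters, slowed ions deposit at raised LET, and Fe with ~20 g/cm²
range contributes only partially. Nuclear reactions inside the tissue are
not modeled, which biases the light-ion mean weights low (the proton mean
QF is ~1.0 here versus ~1.6 for coefficient-based references, and the
per-element C means are ~20 % high-side of reference on QF) while leaving
totals within the validation band. A thin-target estimator
(D = 1.602·10⁻⁹ Gy per keV/µm per cm⁻²) is retained for unit work.

Means and dose equivalents follow the dose-weighted average
⟨w⟩ = Σw·dD/ΣdD and H_E = ΣᵢDᵢ⟨w⟩ᵢ; element-wise and
distribution-level summation agree to 10⁻¹⁰ (tested). The quality factor
is averaged over the dose-vs-LET distribution; the RBE, which depends on
(Z, E) and not on LET alone, is accumulated during energy deposition where
the ion state is known. A DDREF can be applied as a reporting divisor to
the RBE column only (default 1 = off); the QF and RBE dose equivalents
are labelled non-commensurable in all outputs.

## Slab transport

Straight-ahead deterministic transport with three processes per species:
continuous slowing down (range tables per ion and material), exponential
removal with a macroscopic cross section from mass-fraction-weighted
Bradt–Peters cross sections σ = πr₀²(Ap^⅓ + At^⅓ − δ)², r₀ = 1.26 fm,
and secondary-proton production at conserved energy per nucleon with
multiplicity ν(Z) = Z per removed ion. Protons regenerate on inelastic
collisions (ν(1) = 1): the leading nucleon of a p–A collision persists,
which reproduces the proton buildup observed behind hydrogenous shields
and makes nucleon bookkeeping exact in the ν = A mode. Because the cross
sections are energy-independent, attenuation commutes with slowing down:
transmitted primaries receive the closed-form attenuation factor and one
exact full-slab range shift, and the sublayer discretization (default
0.5 g/cm²) only positions secondary birth depths — halving it changes
H_E by well under 1 %.

Two overlap parameters are distinguished. δ = 1.0 in
`fragmentation_cross_section` reproduces measured total reaction cross
sections (Fe+C ≈ 1.3 b). For *removal* in transport the default is
δ = 1.9: a one-group model that turns every interacting heavy ion into
protons discards the dose equivalent that real fragmentation retains in
slightly lighter heavy fragments, so the effective dose-removal cross
section is smaller than the total reaction cross section (~0.7× for Fe on
C). The single value 1.9 was calibrated once against the reference
dose-equivalent reduction trends behind 20 g/cm² slabs and is shared by
all materials and projectiles, leaving the material ordering and spacing
as genuine predictions. Projectiles below 10 MeV/n are excluded from
transport (they stop within micrometers of any shield) but retained in
free-space dosimetry. Target fragmentation, neutrons, photons, pions and
muons are out of scope; published neutron columns reach ~6 % of the
charged-particle H_E at 20 g/cm², so the charged-particle reductions
reported here are slight overestimates of the all-particle case.

## What the defaults reproduce

At package defaults the pipeline yields: LET-spectrum modes 0.83 / 7.5 /
13.4 / 140 keV/µm (He/C/O/Fe); free-space D = 164 mGy/yr,
⟨QF⟩ = 2.80, H_E(ICRP) = 459 mSv/yr, Fe ⟨QF⟩ = 20.7; and H_E(ICRP)
reductions behind 20 g/cm² of 45.6 % (Al), 60.0 % (PE), 53.6 % (CFRP)
with the strict ordering PE > CFRP > Al. These sit within 10–20 % of
Monte-Carlo-plus-coefficient reference studies, which is the accuracy
class claimed: the pipeline is built for trends, orderings and
sensitivity studies at interactive speed, not for absolute dosimetry.
The full default sweep (13 configurations) runs in seconds on one CPU.

## Known limitations

* No nuclear interactions in the tissue phantom → light-ion mean weights
  biased low; the Fe/H mean-QF ratio (~21) is higher than
  coefficient-based references (~11–12).
* One-group fragmentation with proton-only secondaries → shielded LET
  spectra lack the heavy-fragment and target-fragment structure between
  the primary peaks.
* Placeholder RBE parameters → RBE results are shape-only until the
  published endpoint fit is supplied.
* Straight-ahead geometry, isotropy collapsed to a single 4π-integrated
  fluence; no solar-energetic-particle or trapped-radiation components;
  no time-dependent modulation.
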