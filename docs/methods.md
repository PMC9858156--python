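# Methods

## The model

The tissue is a laterally infinite slab of seven plane-parallel skin layers
under air, with a pencil beam entering at the origin along +z. Geometry and
composition of the default stack:

| layer | thickness (mm) | V_blood | V_H2O | V_mel |
|---|---|---|---|---|
| stratum corneum | 0.02 | 0 | 0.05 | 0 |
| epidermis | 0.25 | 0 | 0.20 | 0.02 or 0.20 |
| papillary dermis | 0.10 | 0.04 | 0.50 | 0 |
| upper blood net dermis | 0.08 | 0.30 | 0.60 | 0 |
| reticular dermis | 0.20 | 0.04 | 0.70 | 0 |
| deep blood net dermis | 0.30 | 0.10 | 0.70 | 0 |
| subcutaneous tissue | 2.00 | 0.05 | 0.70 | 0 |

One scattering spectrum is shared by all layers — μs = 60.61, 41.74, 22.33,
15.05, 13.32, 9.5, 7.52 mm⁻¹ at 450, 550, …, 1050 nm — with
Henyey–Greenstein anisotropy g = 0.9 and refractive index n = 1.37 in every
layer (1.0 ambient). g and n are not constrained by the source data for this
stack; 0.9 and 1.37 are the standard soft-tissue values and both are
per-layer configurable. Wavelengths are nearest-grid only (±0.5 nm snap);
there is no interpolation between the seven grid points.

### Absorption

Layer absorption is the volume-fraction blend

μa = V_blood·[S·μa_HbO2 + (1−S)·μa_Hb] + V_H2O·μa_H2O + (1−V_blood−V_H2O)·μa_other

with blood oxygen saturation S = 0.75 (configurable). The epidermis instead
mixes melanin, water and baseline:

μa_epi = V_mel·μa_mel + V_H2O·μa_H2O + (1−V_mel−V_H2O)·μa_other,

where μa_mel(λ) = 6.6×10¹⁰·λ⁻³·³³ mm⁻¹ (λ in nm; the scale constant is
configurable because published variants of this law differ by powers of
ten — this one equals the common 6.6×10¹¹ λ⁻³·³³ cm⁻¹ form). A printed
variant of the epidermis mixture multiplies V_H2O by the oxyhemoglobin
spectrum instead of water; that reading is almost certainly a typographical
slip, but it is selectable (`epidermis_middle_term: hbo2`) rather than
silently discarded.

The chromophore spectra are a literature-standard compilation at the seven
grid wavelengths: Hale–Querry/Segelstein-style pure water, Prahl-style
hemoglobin molar extinctions converted to whole blood at 150 g/L
(μa = ln 10·ε·2.326 mM; the 1050 nm entries extrapolate the 1000 nm end of
the standard tabulation flat), and a flat 2.5×10⁻³ mm⁻¹ baseline for
bloodless dry tissue. All four spectra are replaceable via the YAML
`chromophores` table.

## Transport

Standard weighted-packet multi-layer Monte Carlo: packets launch with weight
1 − R_specular, take exponential steps, split steps at layer interfaces
(conserving the dimensionless residual step when μ changes), deposit
Δw = w·μa/(μa+μs) at each interaction, scatter through the
Henyey–Greenstein inverse CDF with azimuth 2πξ, and undergo unpolarised
Fresnel reflection/refraction (Snell, total internal reflection) wherever
refractive indices differ. Packets escaping the top surface are binned by
exit radius into annular detector rings — the radially symmetric equivalent
of a point detector at (d, 0, 0) — accumulating weight, count, total and
per-layer pathlengths, and their squares (for detection-statistics standard
errors). Packets crossing the bottom of the subcutaneous layer are recorded
as transmitted and killed (the bottom interface is matched; a config flag
makes the last layer semi-infinite instead). Everything that can carry
weight is accounted: specular + detected/reflected + transmitted + absorbed
+ net roulette flow + path-cap losses equals the launched weight to float
precision, and `run_transport` aborts if the residual exceeds 10⁻⁶.

Two step-sampling conventions exist because the two textbook presentations
of the method differ:

* `total` (package default): interaction sites sampled with μt = μa + μs —
  the scheme consistent with the μa/(μa+μs) weight deposit, and unbiased
  for physical detected-photon statistics.
* `scattering`: free paths sampled with μs alone, so the geometry of a
  trajectory is that of the pure scattering process and absorption acts
  only on weights.

Correspondingly, the mean detected pathlength has a weighted
(Σ wᵢLᵢ/Σ wᵢ, default) and an unweighted (plain mean, Eq.-literal) form.

**The scatter-path replication protocol** — `scattering` sampling,
unweighted mean, Russian roulette disabled (photons terminate only by
escaping the finite slab) — is the configuration this package uses to
reproduce published skin DPF tables of this kind. The published values
themselves force this reading: a DPF of ~43 at 450 nm and 8 mm spacing
means a 346 mm mean path, which carries an absorption attenuation factor of
about e⁻⁵⁰⁰ under any realistic blood content (dermis μa ≈ 1.5 mm⁻¹ at
450 nm); inverting the semi-infinite diffusion closed form against such a
table yields μa ≈ 4×10⁻⁴–1.3×10⁻² mm⁻¹, i.e. the published path statistics
are those of an (almost) non-absorbing scattering process. Under the
scatter-path protocol DPF depends only on the scattering spectrum, g, n and
the geometry — all of which are printed — and not on the unprinted
absorption inputs.

Consequences worth knowing before comparing numbers:

* In the finite 2.95 mm stack, pathlength survival decays with constant
  Λ = 3μs′D²_ext/π² ≈ 20 mm at 450 nm, so the short-wavelength DPF
  saturates near 10 with increasing separation instead of climbing to ~40:
  table values that large additionally require an effectively semi-infinite
  medium whose only path cutoff is a very small (unprinted) absorption.
  The package reports what the stated geometry actually produces.
* Under the scatter-path protocol the trajectory of a packet is independent
  of absorption, so the DPF grid is *exactly* identical for 2 % and 20 %
  melanin when common random numbers are used — the skin-color
  insensitivity of this estimator is structural, not statistical. (Under
  the weighted protocol, epidermal melanin does reweight paths by several
  percent in the NIR.)
* The unweighted mean over a semi-infinite non-absorbing medium diverges;
  the `extend_bottom` flag therefore combines meaningfully with the
  scatter-path protocol only via the `max_path` cap, and such numbers are
  cap-dependent. The finite slab is the default for this reason.

## Estimators and statistics

DPF(λ, d) = ⟨L⟩/d over the annulus of width 0.5 mm centred on d (sparse
separation lists get gap rings so each query ring keeps exactly that
width). Empty rings raise an explicit insufficient-statistics error, never
a silent zero. Replicate sweeps run N independently seeded transports per
wavelength (seeds from `SeedSequence(base_seed, stream)`, 31-bit); the grid
carries the across-replicate sample SD (ddof = 1, flagged invalid for
N = 1) *and* the pooled per-cell Monte Carlo SE computed from detection
counts (effective sample size (Σw)²/Σw² for the weighted form). Per-layer
mean partial pathlengths always sum to the total mean path exactly, by
construction of the accounting.

Spatial sensitivity maps accumulate, for detected packets only, the
weight-scaled pathlength spent in each (x, z) bin, after rotating each
trajectory about z so its exit lands at azimuth zero (radial symmetry);
segments are subdivided to half the bin pitch before deposition and the map
is normalised to sum 1. `penetration_depth` reports the depth of the
maximum of the depth-marginal profile, which is more stable than a 2-D
argmax.

## Reference oracles

Three deliberately independent implementations live in `skindpf.oracles`
and share no code with the engine: (1) a pure-Python one-photon-at-a-time
walker with the same physics contract, used to validate the compiled kernel
to 3 combined SE on toy models; (2) the steady-state semi-infinite
diffusion DPF, DPF = ½√(3μs′/μa)·[1 − 1/(1 + d√(3μaμs′))] — accurate only
for μs′ ≫ μa and μ_eff·d ≳ 3, which is where the equivalence tests compare
(nearer the source the dipole formula is low by tens of percent, a property
of the approximation, not of the engine); (3) Gauss quadrature of the
Henyey–Greenstein density for its moments.

## Numerical choices

* Roulette: threshold 10⁻⁴, survival 0.1 (boost ×10); the signed net
  roulette flow is ledgered so per-run conservation stays exact.
* `max_path` safety cap 1000 mm; capped weight is ledgered separately.
* Free-path sampling uses −ln(u) with u ∈ (0, 1]; μ ≤ 0 is rejected at the
  API (a degenerate non-scattering layer is modelled with a tiny μs).
* Direction vectors are renormalised after every rotation; unit norm is a
  tested invariant (1e−9).
* The compiled kernel and the sensitivity tracer run single-threaded with
  the legacy per-kernel RNG seeded per chunk, so every run is bit
  deterministic given (model, config, rings).

## Problem sizes

The production protocol (10⁸ photons × 20 replicates per wavelength, the
`full` CLI preset) is supported but not exercised by the test suite. The
packaged checks use desk-scale budgets chosen for tight-enough statistics:
3×10⁶ photons per wavelength for the headline DPF values
(`scripts/acceptance.py`; SE ≲ 3 % in the worst cell, 450 nm at 8 mm),
3×10⁵ × 2 replicates for the full 7×16 trend grid, 5×10⁴ for
engine-vs-walker equivalence, and 10⁵–3×10⁵ for the physics property
checks.

## Known limitations

* Steady-state only: no time-of-flight, polarisation, or fluorescence; no
  curved geometry; pencil-beam source and annular detection only.
* Optical properties are layer-wise constant and wavelength-gridded; no
  temperature, hydration or age dependence.
* One scattering spectrum serves all layers unless overridden — real
  stratum corneum/subcutis scattering differs.
* The default chromophore table is a compact compilation rounded to ~1 %;
  users replicating a specific published table should substitute the
  compilation that table used (usually unprinted — the dominant source of
  disagreement, far larger than Monte Carlo error).
* Melanin insensitivity under the scatter-path estimator is exact by
  construction (see above), so it validates the accounting, not the
  radiative physics of pigmentation.
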