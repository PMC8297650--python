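# Methods

## Overview

`uvcanopy` models the chain from LED emission to per-leaf absorbed UV
energy to bioactive-compound response in rosette canopies grown under
controlled-environment lighting. The chain has four models: a geometric
canopy model, a radiative transport model, a dosimetric weighting model,
and a statistical response model. This note records the assumptions,
defaults and numerical choices of each, and what the synthetic data can
and cannot establish.

## Canopy geometry

Plants are spiral-phyllotaxis rosettes: leaf of rank *k* (rank 1 = oldest)
sits at azimuth (k−1)·137.5° and attaches at height (k−1)·internode rise.
A blade is a triangulated planar ellipse (4 radial rings × 12 sectors by
default), tilted by an elevation angle from horizontal, with a quadratic
droop of the outer blade (`bend`, fraction of half-length). This is the
simplest surface family that produces realistic self-shading; it makes no
attempt at venation, serration or time-resolved growth, and it is not a
reconstruction of any scanned plant.

Position classes partition ranks from youngest down: the youngest *n_u*
leaves are "upper", then "middle", then "lower". The two presets mirror a
young and an older growth stage:

| preset | leaves | classes (u/m/l) | blade length | elevation | canopy LAI |
|--------|--------|------------------|--------------|-----------|------------|
| 14DAT  | 7      | 3/2/2            | 55→30 mm     | 15–25°    | ≈0.40 at 24 plants/bed |
| 28DAT  | 10     | 4/3/3            | 135→68 mm    | 15–45°    | ≈1.60 at 12 plants/bed |

Older (lower-rank) leaves are larger and flatter; younger leaves smaller
and steeper, which is the usual rosette habit. Blade sizes were calibrated
so a full bed (0.80 × 0.50 m module) lands near leaf area indices of 0.40
and 1.60 for the two stages — the densities the analysis is meant to
contrast. Elevation angles are moderate (≤45°): strongly erect young
leaves would suppress their own horizontal interception through the
cosine factor, which is not the habit of flat rosette crops like kale.
Azimuth (σ = 8°) and elevation (σ = 5°) jitter give seed-to-seed canopy
variation; with jitter disabled the generator is a pure deterministic
function of its parameters.

## Scene and optics

Coordinates are metres, z-up, bed top at z = 0, bed centred on the origin.
LED bars are rectangular Lambertian emitters facing down (default: 4 bars
spanning the bed at 0.45 m — plant-to-lamp distances then fall in the
0.25–0.40 m range typical of multi-tier growth modules). When sources are
specified by a target irradiance E, total power is E × bed area split
equally across bars; because the domain is open (no walls), the realised
bed-plane irradiance is below E and canopy results should be read
relatively, not absolutely.

Optics are band-level (grey per band): each surface class carries
(ρ, τ, α) with ρ + τ + α = 1 per band. Defaults: leaves PAR ρ=0.10,
τ=0.07; leaves UV ρ=0.05, τ=0.01 (epidermal UV screening makes leaves
strongly UV-absorbing); bed ρ=0.50, τ=0 (white module material, diffuse).
The defaults are typical green-leaf values, config-swappable; per-position
measured optics can be supplied per class.

## Monte Carlo transport

Forward tracing from the emitters. Each ray: uniform origin on an
emitting face (faces chosen proportional to power), cosine-weighted
direction; nearest-triangle intersection through a median-split BVH
(two-sided Möller–Trumbore); at each hit exactly one outcome is sampled —
absorb (α), diffuse reflection into the incident hemisphere (ρ), diffuse
transmission into the far hemisphere (τ), both cosine-weighted about the
hit-side normal. Sampling one outcome per hit is the Russian-roulette
variant of interaction sampling: unbiased, constant work per bounce, and
it leaves nothing to re-weight, so emitted = absorbed + escaped holds
*exactly* in every run (the estimator is a partition of ray counts). Rays
exceeding `max_bounces` (default 10) or leaving the open domain count as
escaped.

Each surface tally is binomial: absorbed power = P_total·k/n with standard
error P_total·√(p(1−p)/n). The reported SE therefore scales exactly as
1/√n; its calibration against the seed-to-seed spread of independent runs
is part of the test suite. Randomness is a counter-based splitmix64
stream keyed by (seed, ray index), so tallies are bit-identical for a
fixed seed regardless of batching.

Transmission is diffuse, not refractive; there is no specular component,
polarization or participating medium. Transport is per band (PAR
400–700 nm, UV 250–400 nm); spectral structure within a band is the
dosimetry module's job.

The tracer is validated against `analytic_plate_irradiance`, a
deterministic Gauss–Legendre integration of L·cosθ₁cosθ₂/d² over source
(and receiver) rectangles — the view-factor integral — which reproduces
the πL infinite-plane limit and the inverse-square small-source limit.

## Dosimetry

* Band integration is trapezoidal on the native wavelength grid with
  interpolated band edges; bands are half-open [lo, hi) nm.
* Photon conversion: flux = E·λ/(h·c·N_A) with CODATA-exact constants
  (1 W m⁻² at 310 nm = 2.591 µmol m⁻² s⁻¹).
* The action spectrum is the generalized plant action spectrum in its
  analytic form ε(λ) = 2.618·[1−(λ/313.3)²]·exp(−(λ−300)/31.08) for
  λ < 313.3 nm, renormalised to ε(300 nm) = 1 (ε(310) ≈ 0.183). The
  weighting is exposed two ways: `be_factor(spectrum)` computes
  ∫εE/∫E for any spectrum, and `calibrate_be_factor(dose, be_dose)`
  derives the factor from a stated dose pair. For the six-treatment
  experiment the calibrated factor is 2.1/21.6 ≈ 0.0972; a 10 nm-FWHM
  Gaussian at 310 nm under the analytic ε gives ≈ 0.24. The discrepancy
  is expected — the effective factor depends strongly on the real LED
  spectrum's tails and on the exact action-spectrum formulation, which is
  why the calibrated route exists and is used for reproducing printed BE
  doses.
* Cumulative dose = irradiance × h/day × 3600 × days / 1000 (kJ m⁻²),
  exactly linear in all three factors. The treatment grid is
  {6, 12} h/day × {1, 2, 3} days. The printed dose table of the
  motivating experiment implies an effective plant-level irradiance of
  1.0 W m⁻² (21.6 kJ m⁻² = 1.0 × 6 × 3600/1000), although the lamp is
  described as 1.2 W m⁻²; dose functions therefore take irradiance
  explicitly and `effective_irradiance_from_dose` derives it from a dose,
  asserting neither value as "correct".

## Response statistics

* RSA% = (A_control − A_sample)/A_control × 100; Fv/Fm = (Fm − F0)/Fm,
  with 0.78–0.85 flagged as the unstressed range.
* `fit_linear_yield` is ordinary least squares of concentration on
  cumulative absorbed UV; the slope is the UV energy yield
  (concentration per kJ m⁻² absorbed). R² = 1 − SS_res/SS_tot; a constant
  response is defined to have R² = 0.
* The increase-rate equation "a/ΔUV + b" is typographically ambiguous;
  three parses are implemented — F1: a/(ΔUV+b), F2: a·ΔUV/(ΔUV+b),
  F3: a/ΔUV + b — with F2 (the saturating rectangular hyperbola through
  the origin) as the default, since a monotone saturating dose-response is
  the conventional reading and matches dose-dependent compound increases.
  The form used is always recorded in the fit result. Fitting is
  Levenberg–Marquardt least squares with 5 multi-starts over data-scaled
  (a, b); ties break on lowest SS_res then lowest |b|; non-convergence is
  reported, never swallowed.
* Increase rates are computed against the position-class-matched control
  mean at the same growth stage. Linear fits pool control rows (ΔUV = 0)
  by default (`include_controls`); nonlinear fits use treated rows only,
  since F3 diverges at ΔUV = 0.

## Synthetic assay generator

Concentration = control × (1 + f(ΔUV)/100) + N(0, σ), truncated at 0 (the
scavenging percentage is additionally capped at 100); control rows carry
ΔUV = 0 and f = 0. The generating curve f is any response-curve object
(linear or hyperbolic), which makes the generator its own oracle: with
σ = 0 the fitters must return the generating parameters exactly, and with
noise the recovery error must shrink with n. That is the statistical
structure the analysis assumes — noise independent across leaves and
additive on concentration. Real assay data would add leaf-age
physiology, between-plant correlation and heteroscedasticity; passing the
recovery tests shows the estimators are correct, not that the biology is
linear.

## Pipeline and problem sizes

`run_pipeline` chains the stages from one config and one global seed,
fanned out per stage by a fixed `SeedSequence` spawning rule; reruns are
byte-identical. Default run sizes (200 000 rays per band, 24 or 12
plants, 5 seeds for replicate properties) keep a full desk run in
seconds while leaving Monte Carlo errors at the few-percent level on
per-leaf tallies; ray counts are config parameters, and the validation
tests use 10⁶ rays where 3σ oracle agreement is asserted.

## Known limitations

* Synthetic rosettes, not scanned geometry: figure-level percentages from
  any particular real canopy (e.g. exact upper-vs-lower gaps) are
  scan-specific and are deliberately asserted only as orderings and
  directions of change here.
* Grey-band transport ignores within-band spectral variation of optics.
* The open domain loses side-emitted light; absolute bed-plane irradiance
  is below the nominal target, so absolute tallies should be calibrated
  against a measured reference if needed.
* The bed-area convention for LAI and planting density is ambiguous in
  multi-module setups; `leaf_area_index` takes bed area explicitly and no
  default is asserted.
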