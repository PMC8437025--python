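# Methods

## Model overview

`coralslab` solves the steady physico-chemical microenvironment of a
laterally uniform coral slab in a flow chamber: a collimated light source
above air, a laminar water channel, a stratified tissue (mucus, epidermis,
mesoglea, oral gastrodermis, gastric cavity, aboral gastrodermis, aboral
mesoglea) and a thick aragonite skeleton (calicoblast layer merged into
it). Absorbed light drives heating everywhere and O₂ production in the
symbiont-bearing gastrodermis; respiration consumes O₂ in the gastrodermis
and skeleton. The three stages run in sequence — light → flow → heat → O₂
— because the light field is independent of temperature and chemistry at
this scale, and the flow is prescribed by the channel geometry.

The default parameterization is a thick-tissue faviid-type coral: per-layer
optical properties at 636 nm (inside the chlorophyll a/c absorption window
of the symbionts), thermal and O₂-transport properties per layer, and
flow-chamber conditions (320 µmol photons m⁻² s⁻¹ incident downwelling
irradiance, 0.4 cm s⁻¹ depth-averaged velocity, 25 °C, 0.25 mol m⁻³ inlet
O₂). A 0.1 mm aboral mesoglea with the same properties as the oral
mesoglea is included so the tissue compartment (mucus through aboral
mesoglea) totals 1.7 mm in the contracted state. Air thermal properties
(ρ = 1.184 kg m⁻³, k = 0.026 W m⁻¹ K⁻¹, C_p = 1005 J kg⁻¹ K⁻¹, 25 °C
values) close the conduction path to the temperature-controlled boundary
above the air layer. The gastric cavity is treated as still pure water
(water thermal properties and O₂ diffusivity); the mucus sheet uses tissue
properties.

## Monte Carlo radiative transfer

* **Geometry reduction.** Layers, source and boundary conditions are
  invariant in x and y, so the z-binned tally is the exact lateral average
  of the 3D field and coincides with a mid-domain slice; photon directions
  remain fully 3D. The tally is broadcast across x for the 2D transport
  stage.
* **Transport scheme.** Steps are sampled against the scattering
  coefficient only; absorption attenuates the photon weight continuously,
  exp(−μₐs), along each segment. With the track-length fluence estimator
  this makes the per-bin absorbed weight identically μₐ·φ and the global
  weight balance exact per realization, and a purely absorbing slab
  becomes a zero-variance Beer–Lambert problem. Residual step optical
  depth is carried across layer interfaces, which keeps runs that differ
  in a single coefficient tightly correlated (common random numbers) —
  important for resolving small scenario contrasts such as the low end of
  the epidermal scattering sweep.
* **Scattering and interfaces.** Henyey–Greenstein deflection by CDF
  inversion, uniform azimuth. At every refractive-index mismatch a single
  uniform deviate chooses between specular reflection (unpolarized Fresnel
  reflectance, 1 under total internal reflection) and Snell refraction.
  Layers with g = 1 (air, water, gastric cavity) deflect by exactly zero
  degrees, i.e. pass-through; their μₛ = 10⁻⁵ cm⁻¹ is retained literally.
* **Domain boundaries.** The beam enters at the top of the air layer
  (collimated, normal incidence). The top and bottom domain faces are
  Fresnel interfaces to exterior air (n = 1): weight that refracts out is
  tallied as reflected/transmitted, weight that reflects returns. At the
  skeleton bottom this matters — the n = 1.66→1 mismatch returns most
  diffuse light (critical angle ≈ 37°), so deep light is recycled through
  the aboral tissue instead of vanishing; an open bottom would darken the
  deep profiles unphysically.
* **Termination.** Russian roulette below weight 10⁻⁴ with survival
  probability 0.1; killed and boosted weight are tallied so the balance
  launched = reflected + transmitted + absorbed closes to float roundoff
  (the conservation check in every run demands < 10⁻⁶ relative; measured
  residuals are ~10⁻¹³).
* **RNG.** Each photon owns a counter-based splitmix64 stream derived from
  (seed, photon index): runs are bit-identical for a fixed seed and
  independent of photon batching.
* **Smoothing.** The tallied field can be smoothed with a within-layer
  Gaussian (reflecting ends, default σ = 2 cells). Filtering per layer
  keeps the smoothing conservative (layer-integrated absorbed power
  preserved to roundoff) and prevents absorption from leaking across
  material boundaries. Conservative piecewise-constant rebinning
  (`resample_light_field`) moves a tally between grids without changing
  deposited power.

## Flow

The water layer is the only flowing medium. For a flat slab the steady
unidirectional Stokes problem (Re ≈ 9 at 0.4 cm s⁻¹, inertia negligible)
reduces to η u″(z) = G with no-slip at the coral surface and zero shear at
the air–water interface; the forcing is scaled so the depth-averaged
velocity equals v₀. This is the half-Poiseuille profile u = 1.5 v₀ s(2−s)
(s the fractional height above the wall), solved numerically on the grid
so non-uniform spacings are handled; it is divergence-free identically.

## Heat and O₂ transport

Finite-volume discretization on a shared rectilinear grid, cells uniform
within each layer (default 10 µm vertically — profiles change by < 1 % of
their dynamic range when refined from 20 µm — and 100 µm horizontally);
harmonic-mean diffusive conductances at faces, first-order upwind
advection, sparse direct (LU) solves.

Boundary conditions (a flow chamber with a temperature-controlled bath):

| face | heat | O₂ |
| --- | --- | --- |
| top of air | Dirichlet T₀ | — (air excluded) |
| water inlet (left) | Dirichlet T₀ | Dirichlet c₀ |
| solid left faces | zero flux | zero flux |
| right face | advective outflow (zero diffusive flux) | advective outflow |
| air–water interface | interior | zero flux |
| skeleton bottom | zero flux | zero flux |

The heat equation is solved in elevation form ΔT = T − T₀, so the solution
is exactly linear in the absorbed power (and hence in the incident
irradiance). The heat source is f_heat × absorbed power in the gastrodermis
(f_ps = 0.04 of the absorbed quanta are diverted into photochemistry by
the symbionts) and the full absorbed power elsewhere. Discrete energy and
O₂ balances (volume-integrated source vs. net boundary efflux) are checked
on every run at 10⁻⁴ relative; direct solves leave them at roundoff.

The Monod sink R_max·c/(K_O₂ + c) is resolved by Newton linearization
about the previous iterate (first three iterations damped by 0.8),
converged to a 10⁻⁸ relative change with the nonlinear residual reported;
the non-negative Jacobian term preserves the M-matrix structure so O₂
stays non-negative. R_max is the symbiont light-respiration capacity
(1.2 × 10⁻² mol m⁻³ s⁻¹) in both gastrodermis layers regardless of light
level, and the skeleton consumption rate (3.75 × 10⁻⁵ mol m⁻³ s⁻¹) in the
skeleton; epidermis and mesoglea are assigned no respiration. The gross
photosynthesis-to-respiration ratio is reported as a per-run diagnostic,
not imposed as a constraint.

## Scenarios

All scenarios are pure transformations of the baseline stack; untouched
layers are returned bit-identical.

* **Pigment distribution** — epidermal anisotropy g = 0.34 (granular,
  near-isotropic) or 0.96 (diffuse, forward-peaked); only g changes.
* **Pigment density** — epidermal μₛ over 0.126…1260 cm⁻¹ (five decades).
* **Tissue state** — contracted keeps baseline thicknesses (1.7 mm total);
  sideways expansion halves every tissue-layer thickness (0.85 mm total)
  with volumetric coefficients unchanged, so areal pigment and symbiont
  amounts halve.
* **Mucus production** — mucus thickness 0.05/0.1/0.15 mm.
* **Bleaching** — gastrodermal μₐ interpolates linearly between the
  seawater background (3.6 × 10⁻³ cm⁻¹) and the healthy value with the
  symbiont density fraction; quantum efficiencies scale with the same
  fraction so a fully bleached coral produces no O₂ from residual water
  absorption.

## Metric conventions

* Depth datum: z = 0 at the mucus surface, positive into the coral,
  negative into the water — the orientation of microsensor profiles.
* Boundary-layer thickness: distance above the surface at which the
  deviation from ambient first relaxes to (1 − criterion) of the surface
  deviation, linearly interpolated; criterion defaults to 0.90 and is an
  explicit parameter (there is no universal operational definition).
  Invariant under affine rescaling of the profile.
* Light enhancement: normalized scalar irradiance read at a configurable
  depth. The generic metric reads the tissue surface; the bleaching power
  law is fitted to the enhancement at the top of the oral gastrodermis,
  where the optical feedback acts on the symbionts.
* O₂ peaks: interior local maxima with prominence above 1 % of the profile
  range (configurable), annotated with the containing layer.
* Power-law fits are least squares in log–log space with R² reported on
  that scale.

## Problem sizes

Full-fidelity runs use 10⁶ photons on the 10 µm / 100 µm grid (the
acceptance script and the headline checks); scenario comparisons use
2 × 10⁵ photons with 200 µm horizontal spacing and a shared seed, which the
common-random-number design makes sufficient to resolve even the ~1 %
contrasts at the low end of the scattering sweep. Exploratory runs at
2 × 10⁴ photons on a 20 µm grid complete in a few seconds.

## What the slab does and does not represent

The model mimics flow-chamber microsensor studies: stationary laminar
unidirectional flow, constant bath temperature, moderate single-wavelength
irradiance. Passing its checks therefore says nothing about spectral
effects (no fluorescence, no UV wavelength conversion, no spectrally
resolved absorption), colony-scale 3D morphology (self-shading, flow
recirculation, turbulence), seabed reflectance, ciliary mixing, or
transient dynamics — all outside scope. Metabolism is deliberately simple:
fixed quantum efficiencies with no light saturation or photoinhibition,
and a fixed volumetric respiration capacity. Two consequences are worth
knowing when comparing with published observations: with the fixed
gastrodermal R_max, the aboral gastrodermis is net heterotrophic at
baseline light (its local production ≈ 5 × 10⁻³ mol m⁻³ s⁻¹ is below
R_max), so the model shows a single oral O₂ peak rather than one per
symbiont layer; and in the tissue-expansion scenario the thinner tissue
both funnels photons to the high-efficiency aboral gastrodermis (raising
deep O₂) and halves the conduction resistance to the ambient water
(lowering deep temperature), orderings that reverse some experimentally
reported contracted-vs-expanded contrasts. Both behaviours trace to the
respiration coupling, for which the volumetric conversion from
per-symbiont rates is not well constrained; R_max is an explicit per-layer
parameter for users who wish to explore alternatives.
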