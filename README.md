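# coralslab

A multiphysics model of the physico-chemical microenvironment inside a
flow- and light-exposed coral, for coral photobiologists and
ecophysiologists who interpret microsensor profiles of light, temperature
and O₂ measured in flow chambers.

Reef-building corals are diploblastic animals hosting photosynthetic
dinoflagellates (Symbiodiniaceae) in their gastrodermis. The model
represents a thick-tissue faviid-type coral as a stratified slab — air and
flowing seawater above a mucus-covered multi-layered tissue (epidermis with
scattering host pigments, mesoglea, oral gastrodermis, water-filled gastric
cavity, aboral gastrodermis, aboral mesoglea) on an aragonite skeleton —
and couples three steady problems:

1. **Radiative transfer.** Monte Carlo photon transport at 636 nm with
   Henyey–Greenstein scattering (per-layer μₐ, μₛ, g) and unpolarized
   Fresnel reflection/refraction at every refractive-index mismatch.
   A track-length estimator tallies scalar irradiance φ(z); volumetric
   photon absorption is μₐ·φ.
2. **Heat.** ρC_p **u**·∇T = ∇·(k∇T) + q with q = f_heat·(absorbed power)
   in the symbiont layers (the complement f_ps is diverted into
   photochemistry) and full thermalization elsewhere, under laminar
   channel flow of the water layer (half-Poiseuille, depth-averaged
   velocity v₀).
3. **Oxygen.** **u**·∇c = ∇·(D∇c) + Q·(absorbed photons) −
   R_max·c/(K_O₂ + c), with photosynthetic quantum efficiency Q in the
   gastrodermis and Monod-limited respiration in the gastrodermis and
   skeleton.

The output is the set of mid-domain depth profiles of normalized scalar
irradiance, temperature and O₂, plus derived metrics: surface light
enhancement, maximum tissue temperature elevation, thermal and diffusive
boundary-layer (TBL/DBL) thickness, O₂ peak locations, and the power law
relating light enhancement to symbiont density during bleaching. Scenario
presets cover host-pigment distribution and density, tissue
contraction/expansion, mucus production and bleaching.

## Worked example

```python
from coralslab import (baseline_stack, run_pipeline, extract_profile,
                       max_temperature_elevation, boundary_layer_thickness,
                       surface_enhancement)

stack, domain = baseline_stack()          # default faviid-type parameterization
light, sol = run_pipeline(stack, domain, n_photons=200_000, seed=7, dx=2e-4)

print(f"surface light enhancement : {surface_enhancement(light):.2f}")
print(f"max temperature elevation : {max_temperature_elevation(sol):.3f} C")
temp = extract_profile(sol, "temperature")
oxy = extract_profile(sol, "oxygen")
print(f"TBL thickness             : {boundary_layer_thickness(temp, domain.T0_C).thickness_mm:.2f} mm")
print(f"DBL thickness             : {boundary_layer_thickness(oxy, domain.c0_mol_m3).thickness_mm:.2f} mm")
```

prints

```
surface light enhancement : 2.92
max temperature elevation : 0.111 C
TBL thickness             : 1.01 mm
DBL thickness             : 0.23 mm
```

The enhancement of 2.92 means the scalar irradiance at the coral surface is
almost three times the incident downwelling irradiance — backscatter from
the pigmented epidermis and skeleton plus internal reflection at index
mismatches concentrate light right where the upper symbionts sit. Under
320 µmol photons m⁻² s⁻¹ at 0.4 cm s⁻¹ flow the tissue runs about 0.1 °C
warmer than the ambient water, and the temperature and O₂ gradients relax
to ambient across a ~1 mm thermal and ~0.2 mm diffusive boundary layer.

The same pipeline is scriptable from the shell:

```sh
coralslab presets
coralslab run --scenario baseline --seed 42 --out runs/baseline
coralslab sweep --family bleaching --seed 42 --out runs/bleaching
coralslab validate src/coralslab/presets/baseline.yaml
```

Each run directory contains `profiles.csv`, `lightfield.csv`,
`metrics.json`, `config.yaml` and a `manifest.json` (seed, grids, solver
residuals, conservation balances) that makes the run byte-for-byte
reproducible.

## Layout

| module | contents |
| --- | --- |
| `coralslab.scenarios` | layer stack and run conditions (validated pydantic models), scenario transforms, YAML config I/O, shipped presets |
| `coralslab.photon_mc` | layered Monte Carlo transport, HG/Fresnel/step kernels, light-field smoothing and resampling |
| `coralslab.solvers` | flow/heat/O₂ finite-volume solvers, source construction, full pipeline |
| `coralslab.metrics` | depth profiles, boundary-layer thickness, peaks, power-law fits |
| `coralslab.cli` | `coralslab run/sweep/validate/presets` |

See `docs/methods.md` for the model assumptions, boundary conditions,
numerical choices and known limitations.
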