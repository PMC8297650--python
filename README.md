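# uvcanopy

Quantifying how much UV-B radiation each leaf of a rosette crop actually
absorbs — and what that absorbed energy buys in bioactive compounds.

In plant factories, short pre-harvest UV-B exposure is used to boost
phenolic and flavonoid contents in leafy crops such as kale. The dose that
matters is not what the lamps emit but what each leaf intercepts, and that
changes with leaf position, leaf angle, self-shading and planting density
as the canopy grows. `uvcanopy` provides the full analysis chain:

* **Synthetic 3D rosettes** — spiral-phyllotaxis plants (137.5° divergence)
  with triangulated elliptic blades, position classes (upper/middle/lower,
  youngest first) and growth-stage presets for a young (7-leaf, canopy
  LAI ≈ 0.4) and an older (10-leaf, LAI ≈ 1.6) stand.
* **Scene assembly** — growth bed, rectangular Lambertian LED bars, plants
  placed at the real planting density; per-band surface optics with
  ρ + τ + α = 1.
* **Monte Carlo ray tracing** — forward transport from the emitters with
  one sampled outcome per hit (absorb / diffuse-reflect / diffuse-transmit),
  BVH-accelerated, bit-reproducible per seed, with exact energy balance and
  binomial Monte Carlo errors. Validated against a deterministic
  view-factor oracle.
* **UV-B dosimetry** — band integration, photon conversion
  (E·λ/(h·c·N_A)), the generalized plant action spectrum ε(λ) normalised at
  300 nm, biologically effective doses, and the 6/12 h × 1/2/3 day
  treatment grid.
* **Interception analysis** — per-position means ± SE, vertical profiles,
  leaf area index, and per-leaf cumulative absorbed UV (kJ m⁻²).
* **Response models** — DPPH radical scavenging activity
  (A_control − A_sample)/A_control × 100, Fv/Fm = (Fm − F0)/Fm, linear
  regression of concentration on cumulative absorbed UV whose slope is the
  **UV energy yield** (the UV analogue of radiation use efficiency), and
  the saturating increase-rate model `rate = a·ΔUV/(ΔUV + b)` (two
  alternative hyperbolic parses included).

## Worked example

```python
import numpy as np
import uvcanopy as uc
from uvcanopy.raytracer import TraceConfig, trace
from uvcanopy.analysis import summarize_by_position

rng = np.random.default_rng(0)
plants = []
for i in range(12):
    params = uc.preset_params("28DAT", rng_seed=int(rng.integers(2**31)))
    plant = uc.generate_rosette(params, plant_id=i)
    plants.append(uc.assign_position_classes(plant, uc.PRESET_CLASS_COUNTS["28DAT"]))

bed = (0.8, 0.5)
sources = uc.default_bar_sources(bed, irradiance_W_m2={"UV": 1.0})
scene = uc.build_scene(plants, None, bed, sources)
result = trace(scene, TraceConfig(n_rays=200_000, rng_seed=7, band="UV"))
summary = summarize_by_position(result, scene.plants)
print(summary.by_class)
```

prints

```
  position_class  mean_flux_W_m2  se_flux_W_m2  n_leaves
0          upper        0.316271      0.009396        48
1         middle        0.243010      0.011457        36
2          lower        0.122016      0.007470        36
```

i.e. in the older, denser canopy the upper (youngest) leaves absorb about
0.32 W m⁻² of UV while the lower leaves get only 0.12 W m⁻² — a 159 % gap
driven entirely by geometry, since every leaf shares the same optics. Over
a 3-day, 12 h/day exposure those flux densities integrate to per-leaf
cumulative absorbed UV of roughly 16–41 kJ m⁻², the regressor for the
yield fits.

The `examples/` directory has one short script per capability (dosimetry,
plant generation, canopy tracing, yield regression, full pipeline); each
prints its numbers with a line on what they mean. A thin CLI mirrors the
pipeline stages: `uvcanopy gen-plant`, `build-scene`, `trace`, `dose`,
`analyze`, `fit-yields`, `run`.

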