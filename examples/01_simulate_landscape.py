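"""Simulate a synthetic landscape: covariate stack, occurrences, ecoregions.

Builds a 30 x 30 km landscape with 7 basal-area layers, 6 correlated climate
layers, a road network with derived anthropogenic layers, then draws
occurrence points from a known Bernoulli point process with a latent Matern
field and prints summary statistics of what was generated.
"""

import numpy as np

import spdesdm as s

config = s.LandscapeConfig(extent_km=30.0, resolution_km=1.0, seed=7)
stack = s.simulate_covariates(config)

print(f"{len(stack.layers)} layers on a {stack.grid.nx} x {stack.grid.ny} grid")
for name in ("northern_hardwoods", "mean_annual_temp", "road_density"):
    layer = stack.layers[name]
    print(
        f"  {name:22s} [{stack.units[name]:14s}] "
        f"min {layer.min():7.2f}  mean {layer.mean():7.2f}  max {layer.max():7.2f}"
    )

r = np.corrcoef(
    stack.layers["mean_annual_temp"].ravel(),
    stack.layers["snow_season_length"].ravel(),
)[0, 1]
print(f"realized temp/snow-season correlation: {r:+.2f} "
      f"(target {config.climate_corr[0, 3]:+.2f})")

# ground truth: presence driven by hardwood basal area + a spatial field
truth = s.TrueModel(
    intercept=-0.5,
    coefficients={"northern_hardwoods": 0.8},
    grf_range_km=10.0,
    grf_sd=0.8,
)
occ = s.simulate_occurrences(stack, truth, n_sites=1200, seed=7)
print(f"\n{len(occ.points)} sites, {occ.labels.sum()} presences "
      f"({occ.labels.mean():.1%} prevalence)")

regions = s.make_ecoregions(stack.grid, 4, seed=7)
print(f"{len(regions)} ecoregions tiling {sum(p.area for p in regions):.0f} km^2")
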