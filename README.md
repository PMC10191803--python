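# spdesdm

Hierarchical Bayesian species distribution modelling on planar landscapes:
presence-background occurrence data are modelled as a Bernoulli point
process whose log-odds combine fixed covariate effects with a latent Matérn
Gaussian random field, candidate models are ranked by WAIC in a three-stage
ladder, and the selected model is post-processed into relative selection
strengths, prediction surfaces with and without the spatial field, and
threshold-based validation metrics.

The package is aimed at quantitative ecologists who want this model family
as a plain, testable Python library: every stage runs on synthetic
landscapes with known ground truth, so coefficient recovery, selection
behaviour and validation metrics can be checked against oracles rather than
taken on faith.

## Model

Labels `Z(s) ∈ {0, 1}` at presence and background locations follow

```
Z(s) ~ Bernoulli(π(s))
logit π(s) = β₀ + Σ X_habitat(s) β_habitat + X_climate(s) β_climate
           + Σ X_anthro(s) β_anthro + RF(s) [+ εNN(s)]
```

where covariates are z-scored, `RF(s)` is a zero-mean Gaussian random field
with Matérn (ν = 1) correlation, and `εNN(s)` is an optional clustering
covariate (log distance to the nearest other presence). The field is
represented on a triangulated mesh by the SPDE/GMRF finite-element
construction: with lumped mass matrix `C` and stiffness matrix `G`,

```
Q = τ² (κ⁴ C + 2κ² G + G C⁻¹ G),   κ = √8 / range,   τ = 1/(√(4π) κ σ)
```

is the sparse precision of a field with marginal sd `σ`; `range` follows the
`√(8ν)/κ` convention (correlation ≈ 0.13 at one range). Inference is a
Gaussian (Laplace) approximation to the joint posterior of `(β, RF)` at
hyperparameters chosen by approximate marginal likelihood on a `(range, σ)`
grid; a seeded independence-Metropolis MCMC mode serves as a slow oracle.
Models are compared with `WAIC = −2(lppd − p_waic)` from posterior draws of
the pointwise log-likelihood, and fixed effects are reported as relative
selection strengths `RSS = exp(β)`.

## Worked example

```python
import numpy as np
import spdesdm as s

stack = s.simulate_covariates(s.LandscapeConfig(extent_km=30.0, seed=11))
truth = s.TrueModel(intercept=-0.5,
                    coefficients={"northern_hardwoods": 0.8,
                                  "housing_density": -0.6},
                    grf_range_km=10.0, grf_sd=0.8)
occ = s.simulate_occurrences(stack, truth, n_sites=1200, seed=12)

mesh = s.build_mesh(stack.grid.polygon(), max_edge=3.0, buffer=8.0)
spde = s.SPDEModel.from_mesh(mesh, 10.0, 1.0)
bg = s.background_points(mesh, stack.grid.polygon(), spacing=3.0)
pts = np.vstack([occ.coords, bg.coords])
z = np.concatenate([occ.labels, np.zeros(len(bg.coords), dtype=int)])
design = s.scale_covariates(
    stack.values_at(pts, ["northern_hardwoods", "housing_density"]))

fit = s.fit(s.ModelSpec(("northern_hardwoods", "housing_density")),
            design, z, spde, s.projector(mesh, pts),
            hyper_grid=[(10.0, 1.0)], seed=13)
print(s.rss_table(fit).round(3))
```

prints (run `examples/03_fit_occurrence_model.py` for the full script):

```
                      rss  rss_lower  rss_upper  beta_mean  raw_unit_increment
northern_hardwoods  1.708      1.449      2.014      0.535               4.633
housing_density     0.624      0.531      0.733     -0.472               5.614
```

i.e. one standard deviation more hardwood basal area (≈ 4.6 m²/ha)
multiplies the relative intensity of use by ≈ 1.7 (95% CI 1.4–2.0), and one
sd more housing density reduces it to ≈ 0.62× — both recovering the signs
and approximate sizes of the generating coefficients (+0.8, −0.6 on the
logit scale).

The `examples/` directory has one short script per capability: landscape
simulation, mesh/field fidelity, model fitting, the three-stage WAIC ladder,
and prediction/validation. `run_pipeline(RunConfig(...))` executes the whole
analysis from one (optionally YAML) configuration and writes all artifacts —
selection ledger, fit summary, RSS table, both surfaces, validation report,
ecoregion class proportions, and a seeded run manifest.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch under the given
seed — simulating the landscape and occurrences, building the mesh, running
the full selection ladder, predicting both surfaces and validating them —
and writes the result JSON to `--out`.
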